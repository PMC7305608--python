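"""Differential insolubility ranking, hypothesis tests, and FDR calling.

Two rankings are provided:

* ``method1_rank`` — disease/control fold of mean raw pellet spectral
  counts, with a Wilcoxon rank-sum test on the raw counts and a Welch t
  test on log2(count + 5) quantile-normalized values;
* ``method2_rank`` — contrast of the per-subject pellet/soluble insolubility
  ratios (each subject's pellet normalized to its own soluble fraction),
  tested with Welch's t.

P values are Benjamini-Hochberg adjusted; a protein is called significant
when the adjusted Welch p is below ``alpha`` AND |log2 fold change| exceeds
``lfc_threshold`` (both strict, defaults 0.05 and 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ValidationError
from .io import CountMatrix, SampleManifest
from .normalize import log_transform, quantile_normalize

METHOD_RAW = "raw_ratio"
METHOD_NORM = "fraction_normalized"


@dataclass(frozen=True)
class SignificanceConfig:
    alpha: float = 0.05
    lfc_threshold: float = 0.5
    adjust_method: str = "BH"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValidationError("lfc_threshold must be >= 0")
        if self.adjust_method != "BH":
            raise ValidationError("only Benjamini-Hochberg ('BH') adjustment is shipped")


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def _welch_rows(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t over matching rows of two matrices."""
    nx, ny = X.shape[1], Y.shape[1]
    if nx < 2 or ny < 2:
        raise ValidationError("Welch's t needs >= 2 observations per group")
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx, vy = X.var(axis=1, ddof=1), Y.var(axis=1, ddof=1)
    sx, sy = vx / nx, vy / ny
    se2 = sx + sy
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / (sx**2 / (nx - 1) + sy**2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-variance conventions: equal means -> t=0, p=1; unequal -> p=0
    degenerate = se2 == 0
    if degenerate.any():
        eq = degenerate & (mx == my)
        ne = degenerate & (mx != my)
        t = np.where(eq, 0.0, t)
        p = np.where(eq, 1.0, p)
        t = np.where(ne, np.where(mx > my, np.inf, -np.inf), t)
        p = np.where(ne, 0.0, p)
        df = np.where(degenerate, float(nx + ny - 2), df)
    return t, df, p


def welch_t(x, y) -> WelchResult:
    """Welch's unequal-variance t test, two-tailed.

    Degenerate inputs (both samples zero variance) return p = 1 when the
    means are equal and p = 0 otherwise.
    """
    X = np.asarray(x, dtype=float)[None, :]
    Y = np.asarray(y, dtype=float)[None, :]
    t, df, p = _welch_rows(X, Y)
    return WelchResult(float(t[0]), float(df[0]), float(p[0]))


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-tailed rank-sum p by dynamic programming (no ties)."""
    n1, n = len(x), len(x) + len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = int(round(ranks[:n1].sum()))
    # dp[k][s] = number of k-subsets of ranks 1..r with rank sum s
    max_sum = n * (n + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    dist = dp[n1]
    total = dist.sum()
    lo = dist[: w + 1].sum() / total
    hi = dist[w:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-tailed Wilcoxon rank-sum p value.

    Exact enumeration of the rank-sum null when the combined sample size is
    at most 12 and there are no ties; otherwise the normal approximation
    with tie correction and a 0.5 continuity correction. All values tied
    across both samples gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    n = n1 + n2
    has_ties = len(np.unique(combined)) < n
    if n <= 12 and not has_ties:
        return _rank_sum_exact_p(x, y)
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(
    manifest: SampleManifest, counts: CountMatrix, group: str, fraction: str
) -> list[str]:
    cols = [s for s in manifest.samples(group=group, fraction=fraction) if s in counts.sample_ids]
    if len(cols) < 2:
        raise ValidationError(
            f"group {group!r} ({fraction}) has {len(cols)} replicate(s); need >= 2"
        )
    return cols


def method1_rank(
    counts: CountMatrix,
    manifest: SampleManifest,
    disease: str = "AD",
    control: str = "control",
    fraction: str = "pellet",
    pseudo_count: int = 5,
) -> pd.DataFrame:
    """Disease/control fold of mean raw spectral counts in one fraction.

    The fold is mean(disease)/mean(control) on raw counts; when the control
    mean is 0 both means are shifted by the pseudo count so control-absent
    proteins get a finite fold. Wilcoxon rank-sum is run on raw counts and
    Welch's t on log2(count + pseudo) quantile-normalized values (normalized
    jointly over the selected columns of the contrast).
    """
    d_cols = _group_columns(manifest, counts, disease, fraction)
    c_cols = _group_columns(manifest, counts, control, fraction)
    sub = counts.subset_samples(d_cols + c_cols)
    norm = quantile_normalize(log_transform(sub, pseudo_count))

    D = sub.counts[d_cols].to_numpy(dtype=float)
    C = sub.counts[c_cols].to_numpy(dtype=float)
    mean_d, mean_c = D.mean(axis=1), C.mean(axis=1)
    ratio = np.where(
        mean_c > 0,
        np.divide(mean_d, mean_c, out=np.full_like(mean_d, np.nan), where=mean_c > 0),
        (mean_d + pseudo_count) / (mean_c + pseudo_count),
    )
    # zero disease mean over nonzero control is a true 0-fold; log handled below
    with np.errstate(divide="ignore"):
        log_fc = np.log2(ratio)

    p_wilcoxon = np.array(
        [wilcoxon_rank_sum(D[i], C[i]) for i in range(D.shape[0])]
    )
    _, _, p_welch = _welch_rows(
        norm[d_cols].to_numpy(), norm[c_cols].to_numpy()
    )
    records = pd.DataFrame(
        {
            "protein_id": sub.protein_ids,
            "method": METHOD_RAW,
            "ratio": ratio,
            "log_fc": log_fc,
            "p_wilcoxon": p_wilcoxon,
            "p_welch": p_welch,
            "q_wilcoxon": bh_adjust(p_wilcoxon),
            "q_welch": bh_adjust(p_welch),
        }
    )
    return records


def method2_rank(
    ratios: pd.DataFrame,
    manifest: SampleManifest,
    disease: str = "AD",
    control: str = "control",
) -> pd.DataFrame:
    """Contrast of per-subject insolubility ratios between two groups.

    log_fc is mean(disease ratios) - mean(control ratios) per protein (log2
    units, fold = 2**log_fc), tested with Welch's t on the two per-subject
    ratio samples.
    """
    group_of = manifest.group_of_subject()
    d_subj = [s for s in ratios.columns if group_of.get(s) == disease]
    c_subj = [s for s in ratios.columns if group_of.get(s) == control]
    if len(d_subj) < 2 or len(c_subj) < 2:
        raise ValidationError("need >= 2 subjects per group for the ratio contrast")
    D = ratios[d_subj].to_numpy()
    C = ratios[c_subj].to_numpy()
    log_fc = D.mean(axis=1) - C.mean(axis=1)
    _, _, p_welch = _welch_rows(D, C)
    return pd.DataFrame(
        {
            "protein_id": list(ratios.index),
            "method": METHOD_NORM,
            "ratio": 2.0**log_fc,
            "log_fc": log_fc,
            "p_wilcoxon": np.nan,
            "p_welch": p_welch,
            "q_wilcoxon": np.nan,
            "q_welch": bh_adjust(p_welch),
        }
    )


def call_significant(
    records: pd.DataFrame, config: SignificanceConfig = SignificanceConfig()
) -> pd.DataFrame:
    """Flag records with adjusted Welch p < alpha AND |log_fc| > threshold."""
    out = records.copy()
    out["significant"] = (out["q_welch"] < config.alpha) & (
        out["log_fc"].abs() > config.lfc_threshold
    )
    return out
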