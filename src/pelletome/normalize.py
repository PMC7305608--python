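"""Count normalization: pseudo-count log2 transform, then quantile normalization.

Spectral counts are shifted by a pseudo count (default 5) before the log2
transform so that undetected proteins (count 0) map to a finite value
instead of -inf, and the log counts are then quantile-normalized so every
sample shares one empirical distribution while within-sample ranks are
preserved. The normalized values feed the per-subject pellet/soluble
insolubility ratio downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .io import CountMatrix, SampleManifest

QN_SCOPES = ("all_samples", "per_fraction")


@dataclass(frozen=True)
class NormalizationConfig:
    """Pseudo count added before log2, and the quantile-normalization scope.

    ``all_samples`` (default) normalizes soluble and pellet columns against a
    single reference distribution; ``per_fraction`` normalizes each fraction
    separately (requires a manifest).
    """

    pseudo_count: int = 5
    qn_scope: str = "all_samples"

    def __post_init__(self) -> None:
        if self.pseudo_count < 0:
            raise ValidationError("pseudo_count must be >= 0")
        if self.qn_scope not in QN_SCOPES:
            raise ValidationError(f"qn_scope must be one of {QN_SCOPES}")


def log_transform(counts: CountMatrix, pseudo_count: int = 5) -> pd.DataFrame:
    """Elementwise ``log2(count + pseudo_count)``, shape preserved.

    A pseudo count of 0 with any zero count would produce -inf and raises.
    """
    arr = counts.counts.to_numpy(dtype=float)
    if pseudo_count == 0 and (arr == 0).any():
        raise ValidationError("pseudo_count 0 with zero counts would give -inf")
    return pd.DataFrame(
        np.log2(arr + pseudo_count), index=counts.counts.index, columns=counts.counts.columns
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted values. Within a
    column, tied values receive the mean of the reference values their sorted
    positions span. The map is rank-preserving, and idempotent on tie-free
    columns; tie averaging perturbs a tied column's value multiset, so exact
    idempotence cannot hold in general under this (standard) convention.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    if matrix.isna().to_numpy().any():
        raise ValidationError("quantile normalization requires complete data")
    X = matrix.to_numpy(dtype=float)
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="mergesort")
        col = np.empty(n)
        col[order] = reference
        # ties: average the reference values spanned by equal inputs
        s = pd.Series(col).groupby(pd.Series(X[:, j])).transform("mean")
        out[:, j] = s.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def normalize_counts(
    counts: CountMatrix,
    config: NormalizationConfig = NormalizationConfig(),
    manifest: SampleManifest | None = None,
) -> pd.DataFrame:
    """log2(count + pseudo) then quantile normalization at the configured scope."""
    logged = log_transform(counts, config.pseudo_count)
    if config.qn_scope == "all_samples":
        return quantile_normalize(logged)
    if manifest is None:
        raise ValidationError("per_fraction scope requires a manifest")
    pieces = []
    for fraction in ("soluble", "pellet"):
        cols = [s for s in manifest.samples(fraction=fraction) if s in logged.columns]
        if cols:
            pieces.append(quantile_normalize(logged[cols]))
    merged = pd.concat(pieces, axis=1)
    return merged[logged.columns.intersection(merged.columns)]
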