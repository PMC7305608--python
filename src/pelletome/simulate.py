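"""Synthetic pelletome data with known ground truth.

The generator emulates the statistical structure of a paired-fraction
spectral-count study: per-protein total abundance (log-normal across
proteins) times a per-sample depth factor gives the expected total count
for a subject; that total is split between the pellet and soluble
fractions by a per-protein partition, and counts are drawn negative
binomial per fraction to capture overdispersion. Disease acts on the
partition (a shift on the base-2 logit scale), not on total abundance, so
the per-subject insolubility ratio is the natural estimand: a logit-2
shift of ``e`` moves the expected pellet/soluble log2 ratio by exactly
``e``. An optional outlier subject has its entire pellet column inflated
by a global multiplicative factor — the minimal mechanism a PC plot
reveals. Companion generators produce gel-slice tables with planted
anomalous migrators and densitometry band tables with planted effects.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .gel import GEL_COLUMNS
from .io import CountMatrix, SampleManifest, SampleRecord


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the paired-fraction count simulator.

    Defaults mirror the motivating cohort design: 8 subjects per group,
    ~3000 proteins, 10% of proteins with a one-log2-unit disease shift of
    the pellet partition.
    """

    n_per_group: int = 8
    n_proteins: int = 3000
    frac_shifted: float = 0.1
    effect_log2: float = 1.0
    baseline_abundance: tuple[float, float] = (4.5, 0.8)  # ln-scale location, scale
    dispersion: float = 20.0  # negative-binomial size; smaller = more overdispersed
    depth_range: tuple[float, float] = (0.8, 1.25)
    pellet_share_range: tuple[float, float] = (0.25, 0.75)
    outlier_subject: bool = False
    outlier_displacement: float = 2.0  # log2-sd of the per-protein pellet distortion
    disease_group: str = "AD"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if not 0.0 <= self.frac_shifted <= 1.0:
            raise ValidationError("frac_shifted must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValidationError("depth_range must be a positive, ordered interval")
        lo, hi = self.pellet_share_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("pellet_share_range must lie strictly inside (0, 1)")
        if self.outlier_displacement < 0:
            raise ValidationError("outlier_displacement must be >= 0")


@dataclass(frozen=True)
class SimulatedDataset:
    counts: CountMatrix
    manifest: SampleManifest
    truth: pd.DataFrame = field(repr=False)  # protein_id, shifted, true_effect_log2
    outlier_subject: str | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    p = size_param / (size_param + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size_param, p)


def simulate_pelletome(config: SimulationConfig) -> SimulatedDataset:
    """Draw a paired soluble/pellet count matrix with known shifted proteins.

    Returns counts (proteins x 2*groups*subjects samples), the manifest, a
    truth table marking shifted proteins and their signed log2 partition
    shift, and (when enabled) the identity of the planted outlier subject.
    Identical config (including seed) gives bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_prot, n_sub = config.n_proteins, config.n_per_group
    protein_ids = [f"P{i:05d}" for i in range(1, n_prot + 1)]

    loc, scale = config.baseline_abundance
    abundance = rng.lognormal(loc, scale, size=n_prot)
    pellet_share = rng.uniform(*config.pellet_share_range, size=n_prot)
    n_shifted = int(round(config.frac_shifted * n_prot))
    shifted_idx = rng.choice(n_prot, size=n_shifted, replace=False)
    shifted = np.zeros(n_prot, dtype=bool)
    shifted[shifted_idx] = True
    effect = np.where(shifted, config.effect_log2, 0.0)
    if config.effect_log2 == 0.0:
        shifted = np.zeros(n_prot, dtype=bool)  # zero shift is no shift

    # disease partition: base-2 logit shift of the pellet share
    odds = pellet_share / (1.0 - pellet_share)
    odds_disease = odds * 2.0**effect
    share_disease = odds_disease / (1.0 + odds_disease)

    groups = [("control", "C"), (config.disease_group, config.disease_group)]
    records: list[SampleRecord] = []
    columns: dict[str, np.ndarray] = {}
    outlier_subject: str | None = None
    # separate stream: planting an outlier must not perturb any other draw
    out_rng = np.random.default_rng((config.seed, 17))
    if config.outlier_subject and config.outlier_displacement > 0:
        outlier_subject = f"{config.disease_group}{out_rng.integers(1, n_sub + 1)}"

    for group, prefix in groups:
        share = pellet_share if group == "control" else share_disease
        for j in range(1, n_sub + 1):
            subject = f"{prefix}{j}"
            depth = rng.uniform(*config.depth_range)
            total = abundance * depth
            mu_pellet = total * share
            mu_soluble = total * (1.0 - share)
            if subject == outlier_subject:
                # compositional scrambling of the pellet column: independent
                # per-protein distortions survive quantile normalization,
                # unlike a uniform column factor (rank-preserving, hence
                # erased by QN before it could reach the PC scores)
                distortion = out_rng.normal(0.0, config.outlier_displacement, size=n_prot)
                mu_pellet = mu_pellet * 2.0**distortion
            age = float(rng.integers(70, 96))
            for fraction, mu in (("soluble", mu_soluble), ("pellet", mu_pellet)):
                sample_id = f"{subject}_{fraction[:3]}"
                columns[sample_id] = _nb_draw(rng, mu, config.dispersion)
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        subject_id=subject,
                        group=group,
                        fraction=fraction,
                        age=age,
                        sex="F",
                    )
                )

    counts = CountMatrix(
        pd.DataFrame(columns, index=protein_ids).astype(np.int64)
    )
    truth = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "shifted": shifted,
            "true_effect_log2": np.where(shifted, config.effect_log2, 0.0),
        }
    )
    return SimulatedDataset(
        counts=counts,
        manifest=SampleManifest(tuple(records)),
        truth=truth,
        outlier_subject=outlier_subject,
    )


def simulate_outlier(config: SimulationConfig) -> SimulatedDataset:
    """Simulate with the planted-outlier channel switched on.

    One disease subject's pellet column is globally inflated by
    ``2**outlier_displacement``; a displacement of 0 plants nothing.
    """
    return simulate_pelletome(replace(config, outlier_subject=True))


# gel fraction bounds: fraction 1 = top of the gel (highest apparent MW)
GEL_FRACTION_BOUNDS = (
    (200.0, 400.0),
    (150.0, 200.0),
    (120.0, 150.0),
    (100.0, 120.0),
    (85.0, 100.0),
    (70.0, 85.0),
    (60.0, 70.0),
    (50.0, 60.0),
    (40.0, 50.0),
    (10.0, 40.0),
)


def simulate_gel_fractions(
    n_proteins: int = 60,
    n_aggregated: int = 11,
    fold_range: tuple[float, float] = (60.0, 300.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Gel-slice count table with planted anomalous migrators.

    ``n_aggregated`` proteins get a predicted mass of 51 kDa or less but are
    placed in fraction 1 (apparent MW > 200 kDa) with a disease/control fold
    drawn from ``fold_range`` (pseudo-count-5 guarded, rounded up so the
    drawn fold is a lower bound). The remaining proteins are placed in the
    fraction matching their predicted mass with exchangeable counts.
    """
    if n_aggregated > n_proteins:
        raise ValidationError("n_aggregated must be <= n_proteins")
    if fold_range[0] <= 0 or fold_range[1] < fold_range[0]:
        raise ValidationError("fold_range must be a positive, ordered interval")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_aggregated):
        pid = f"AGG{i + 1:03d}"
        predicted = float(rng.uniform(15.0, 51.0)) if i else 51.0  # keep one at the boundary
        fold = rng.uniform(*fold_range)
        cc = int(rng.integers(0, 3))
        cd = int(np.ceil(fold * (cc + 5) - 5))
        low, high = GEL_FRACTION_BOUNDS[0]
        rows.append((pid, 1, low, high, predicted, cd, cc))
    for i in range(n_proteins - n_aggregated):
        pid = f"REG{i + 1:03d}"
        predicted = float(rng.uniform(12.0, 380.0))
        frac_idx = next(
            idx
            for idx, (low, high) in enumerate(GEL_FRACTION_BOUNDS, start=1)
            if low <= predicted < high or (idx == 1 and predicted >= high)
        )
        low, high = GEL_FRACTION_BOUNDS[frac_idx - 1]
        cd = int(rng.poisson(30))
        cc = int(rng.poisson(30))
        rows.append((pid, frac_idx, low, high, predicted, cd, cc))
    return pd.DataFrame(rows, columns=list(GEL_COLUMNS))


def simulate_densitometry(
    protein_ids: list[str],
    effect_map: dict[tuple[str, str, str], float],
    n_replicates: int = 4,
    groups: tuple[str, ...] = ("control", "MCI", "AD"),
    fractions: tuple[str, ...] = ("soluble", "pellet"),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SampleManifest]:
    """Band-quantification table with planted per-group relative levels.

    ``effect_map`` maps (protein_id, group, fraction) to the multiplicative
    level versus control (missing keys default to 1; the control group is
    always 1). Band intensity = per-protein baseline x effect x log-normal
    noise x the lane's total-protein signal, so the normalized level
    recovers baseline x effect exactly at noise 0.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if "control" not in groups:
        raise ValidationError("groups must include 'control'")
    rng = np.random.default_rng(seed)
    baseline = {pid: float(rng.lognormal(np.log(0.05), 0.4)) for pid in protein_ids}
    records: list[SampleRecord] = []
    rows = []
    for group in groups:
        for j in range(1, n_replicates + 1):
            subject = f"{group}-s{j}"
            for fraction in fractions:
                sample_id = f"{subject}-{fraction[:3]}"
                records.append(
                    SampleRecord(
                        sample_id=sample_id,
                        subject_id=subject,
                        group=group,
                        fraction=fraction,
                    )
                )
                lane_total = float(rng.lognormal(np.log(100.0), 0.2))
                for pid in protein_ids:
                    eff = 1.0 if group == "control" else effect_map.get((pid, group, fraction), 1.0)
                    noise = float(rng.lognormal(0.0, noise_sd)) if noise_sd > 0 else 1.0
                    rows.append(
                        {
                            "sample_id": sample_id,
                            "protein_id": pid,
                            "band_intensity": baseline[pid] * eff * noise * lane_total,
                            "lane_total": lane_total,
                        }
                    )
    return pd.DataFrame(rows), SampleManifest(tuple(records))
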