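"""SDS-stable aggregate detection from gel-slice spectral counts.

A whole-lane SDS-PAGE gel is cut into 10 fractions of decreasing apparent
molecular weight (fraction 1 = top, highest MW). A low-MW protein observed
in a high-MW fraction migrated anomalously — the signature of an SDS-stable
aggregate. Flagged proteins are ranked by the disease/control fold of their
spectral counts (pseudo-count guarded) and counted above a fold cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from ._errors import ValidationError

GEL_COLUMNS = (
    "protein_id",
    "fraction_index",
    "apparent_mw_low",
    "apparent_mw_high",
    "predicted_mw",
    "count_disease",
    "count_control",
)


@dataclass(frozen=True)
class MigrationConfig:
    """Thresholds for the anomalous-migration rule.

    ``high_mw_cutoff``: apparent MW (kDa) above which a fraction counts as
    high-MW (default 200). ``predicted_max``: largest predicted mass (kDa)
    still considered low-MW, inclusive (default 51, the mass of tubulin).
    ``fold_cutoff``: strict disease/control fold threshold (default 50).
    ``pseudo_count``: added to both counts before the fold (default 5).
    """

    high_mw_cutoff: float = 200.0
    predicted_max: float = 51.0
    fold_cutoff: float = 50.0
    pseudo_count: float = 5.0

    def __post_init__(self) -> None:
        for name in ("high_mw_cutoff", "predicted_max", "fold_cutoff", "pseudo_count"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


def validate_gel_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(GEL_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"gel table missing column(s): {sorted(missing)}")
    if ((table["count_disease"] < 0) | (table["count_control"] < 0)).any():
        raise ValidationError("gel counts must be >= 0")
    bounds = (
        table[["fraction_index", "apparent_mw_low", "apparent_mw_high"]]
        .drop_duplicates()
        .sort_values("fraction_index")
    )
    if (bounds["apparent_mw_low"] >= bounds["apparent_mw_high"]).any():
        raise ValidationError("each fraction needs apparent_mw_low < apparent_mw_high")
    lows = bounds["apparent_mw_low"].to_numpy()
    highs = bounds["apparent_mw_high"].to_numpy()
    if not all(highs[i + 1] <= lows[i] for i in range(len(bounds) - 1)):
        raise ValidationError("fraction MW bounds must be non-overlapping and decreasing")
    return table


def flag_aggregated(table: pd.DataFrame, config: MigrationConfig = MigrationConfig()) -> set[str]:
    """Proteins observed in a high-MW fraction despite a low predicted mass.

    Observed means count_disease + count_control > 0 in a fraction whose
    lower apparent-MW bound is at or above ``high_mw_cutoff``; low predicted
    mass means predicted_mw <= ``predicted_max`` (boundary inclusive).
    Observed proteins with missing predicted_mw are excluded with a warning.
    """
    table = validate_gel_table(table)
    high = table[
        (table["apparent_mw_low"] >= config.high_mw_cutoff)
        & (table["count_disease"] + table["count_control"] > 0)
    ]
    no_mw = high[high["predicted_mw"].isna()]
    if len(no_mw):
        warnings.warn(
            f"excluding protein(s) without predicted_mw: {sorted(no_mw['protein_id'].unique())}",
            stacklevel=2,
        )
    kept = high[high["predicted_mw"].notna() & (high["predicted_mw"] <= config.predicted_max)]
    return set(kept["protein_id"])


def fold_enrichment(
    table: pd.DataFrame, config: MigrationConfig = MigrationConfig()
) -> pd.DataFrame:
    """Pseudo-count-guarded disease/control fold per (protein, fraction)."""
    table = validate_gel_table(table)
    out = table[["protein_id", "fraction_index", "apparent_mw_low"]].copy()
    c = config.pseudo_count
    out["fold"] = (table["count_disease"] + c) / (table["count_control"] + c)
    return out


def count_highly_enriched(
    flagged: set[str], folds: pd.DataFrame, config: MigrationConfig = MigrationConfig()
) -> int:
    """Flagged proteins whose high-MW-fraction fold strictly exceeds the cutoff."""
    high = folds[
        folds["protein_id"].isin(flagged)
        & (folds["apparent_mw_low"] >= config.high_mw_cutoff)
        & (folds["fold"] > config.fold_cutoff)
    ]
    return high["protein_id"].nunique()
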