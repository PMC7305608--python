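"""Western-blot densitometry: relative levels, heatmap binning, correlations.

Band intensities are normalized to the lane's total-protein signal, then
each (protein, group, fraction) mean is expressed relative to the control
group of the same fraction (control = 1 by construction). Relative levels
are binned for a heatmap: a 5% or less deviation from 1 is "no change"
(white); decreases are binned on percent decrease in 20-point steps down
to -5 (shades of blue); increases mirror that up to 2-fold, with a coarse
(2, 4]-fold bin and saturation above 4-fold (dark red).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ValidationError
from .io import SampleManifest

BIN_LABELS = {
    -5: "darkest blue",
    -4: "dark blue",
    -3: "medium blue",
    -2: "blue",
    -1: "light blue",
    0: "white",
    1: "light red",
    2: "red",
    3: "medium red",
    4: "strong red",
    5: "deep red",
    6: "darker red",
    7: "dark red",
}

DEFAULT_ANCHORS = ("Abeta", "tau", "ApoE")


def normalize_band(band_intensity: float, lane_total: float) -> float:
    """Band signal divided by the lane's total-protein signal."""
    if lane_total <= 0:
        raise ValidationError("lane_total must be > 0")
    if band_intensity < 0:
        raise ValidationError("band_intensity must be >= 0")
    return band_intensity / lane_total


def normalized_levels(bands: pd.DataFrame) -> pd.DataFrame:
    """Add a ``level`` column (intensity / lane_total) to a band table."""
    required = {"sample_id", "protein_id", "band_intensity", "lane_total"}
    missing = required - set(bands.columns)
    if missing:
        raise ValidationError(f"band table missing column(s): {sorted(missing)}")
    if (bands["lane_total"] <= 0).any():
        raise ValidationError("lane_total must be > 0 for every band")
    out = bands.copy()
    out["level"] = out["band_intensity"] / out["lane_total"]
    return out


def relative_level(
    bands: pd.DataFrame, manifest: SampleManifest, control_group: str = "control"
) -> pd.DataFrame:
    """Group-mean normalized level relative to the control mean per fraction.

    Returns one row per (protein_id, group, fraction) with
    level = mean(group) / mean(control, same fraction); the control group
    maps to 1. A zero control mean makes the level undefined: reported as
    missing with a warning.
    """
    levels = normalized_levels(bands)
    meta = manifest.to_frame()[["sample_id", "group", "fraction"]]
    merged = levels.merge(meta, on="sample_id", how="left")
    if merged["group"].isna().any():
        stray = sorted(merged.loc[merged["group"].isna(), "sample_id"].unique())
        raise ValidationError(f"band sample(s) missing from manifest: {stray}")
    means = (
        merged.groupby(["protein_id", "fraction", "group"], sort=False)["level"]
        .mean()
        .reset_index()
    )
    control = means[means["group"] == control_group].set_index(["protein_id", "fraction"])[
        "level"
    ]
    rows = []
    for _, row in means.iterrows():
        key = (row["protein_id"], row["fraction"])
        base = control.get(key)
        if base is None or base == 0 or pd.isna(base):
            warnings.warn(
                f"control mean unavailable/zero for {key}; relative level missing",
                stacklevel=2,
            )
            rel = np.nan
        else:
            rel = row["level"] / base
        rows.append(
            {
                "protein_id": row["protein_id"],
                "group": row["group"],
                "fraction": row["fraction"],
                "level": rel,
            }
        )
    return pd.DataFrame(rows)


def heatmap_bin(level: float) -> tuple[int, str]:
    """Signed heatmap bin and color label for a relative level.

    Bin 0 (white) covers |level - 1| <= 0.05. Decreases bin the percent
    decrease in (5,20], (20,40], (40,60], (60,80], (80,100] as -1..-5;
    increases mirror that as +1..+5 up to 2-fold, with (2,4]-fold as +6 and
    > 4-fold saturating at +7 (dark red). Non-decreasing step function of
    the level.
    """
    if not (level > 0) or not math.isfinite(level):
        raise ValidationError("relative level must be a finite positive number")
    if abs(level - 1.0) <= 0.05 + 1e-12:
        b = 0
    elif level < 1.0:
        d = (1.0 - level) * 100.0  # percent decrease in (5, 100)
        b = -min(5, int(math.ceil((d - 1e-12) / 20.0)))
    elif level <= 2.0:
        i = (level - 1.0) * 100.0
        b = min(5, int(math.ceil((i - 1e-12) / 20.0)))
    elif level <= 4.0:
        b = 6
    else:
        b = 7
    return b, BIN_LABELS[b]


def classify_change(level: float) -> str:
    """'unchanged' within the 5% band around 1, else sign of (level - 1)."""
    if not (level > 0):
        raise ValidationError("relative level must be > 0")
    if abs(level - 1.0) <= 0.05 + 1e-12:
        return "unchanged"
    return "increased" if level > 1.0 else "decreased"


def heatmap_cells(levels: pd.DataFrame) -> pd.DataFrame:
    """Bin + color label + change class for a relative-level table."""
    out = levels.dropna(subset=["level"]).copy()
    bins, labels_, classes = [], [], []
    for lv in out["level"]:
        b, lab = heatmap_bin(float(lv))
        bins.append(b)
        labels_.append(lab)
        classes.append(classify_change(float(lv)))
    out["bin"] = bins
    out["color_label"] = labels_
    out["change"] = classes
    return out


def pairwise_correlation(
    levels: pd.DataFrame,
    anchors: Sequence[str] = DEFAULT_ANCHORS,
    others: Iterable[str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlations between anchor and other proteins across subjects.

    ``levels`` is a wide table, subjects (rows) x proteins (columns), of
    per-subject normalized levels within one cohort/fraction. Pairs with
    fewer than ``min_n`` complete observations are dropped with a note;
    zero variance in either vector makes r undefined (reported missing).
    """
    cols = list(levels.columns)
    anchor_list = [a for a in anchors if a in cols]
    other_list = [o for o in (others if others is not None else cols) if o in cols]
    rows = []
    for a in anchor_list:
        for o in other_list:
            if o == a:
                continue
            pair = levels[[a, o]].dropna()
            if len(pair) < min_n:
                rows.append({"anchor": a, "protein_id": o, "n": len(pair), "r": np.nan, "p": np.nan, "note": "too few observations"})
                continue
            x, y = pair[a].to_numpy(), pair[o].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"anchor": a, "protein_id": o, "n": len(pair), "r": np.nan, "p": np.nan, "note": "zero variance"})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"anchor": a, "protein_id": o, "n": len(pair), "r": float(r), "p": float(p), "note": ""})
    return pd.DataFrame(rows, columns=["anchor", "protein_id", "n", "r", "p", "note"])
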