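"""The per-subject insolubility ratio and expression-filter summaries.

The core statistic is the pellet-to-soluble ratio: for each subject the
log2 difference between a protein's normalized pellet and soluble values.
Positive means preferential accumulation in the detergent-insoluble pellet,
negative means preferential accumulation in the soluble supernatant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from ._errors import PairingError, ValidationError
from .io import CountMatrix, SampleManifest


def insolubility_ratio(
    norm: pd.DataFrame, pairing: Mapping[str, tuple[str, str]]
) -> pd.DataFrame:
    """Per-subject log2(pellet) - log2(soluble), proteins x subjects.

    ``pairing`` maps subject -> (soluble sample, pellet sample); both columns
    must be present in the normalized matrix.
    """
    missing = [
        s for sol, pel in pairing.values() for s in (sol, pel) if s not in norm.columns
    ]
    if missing:
        raise PairingError(f"paired sample(s) missing from normalized matrix: {missing}")
    data = {
        subject: norm[pellet] - norm[soluble]
        for subject, (soluble, pellet) in pairing.items()
    }
    return pd.DataFrame(data, index=norm.index)


def expression_filter(
    counts: CountMatrix, manifest: SampleManifest, group: str, fraction: str
) -> set[str]:
    """Proteins detected in a strict majority of a (group, fraction) cell.

    Kept iff the number of replicates with count > 0 exceeds half the number
    of replicates; at even n the exact-half case is excluded.
    """
    cols = [s for s in manifest.samples(group=group, fraction=fraction) if s in counts.sample_ids]
    if not cols:
        raise ValidationError(f"no replicates for group={group!r}, fraction={fraction!r}")
    sub = counts.counts[cols]
    nonzero = (sub > 0).sum(axis=1)
    keep = nonzero > len(cols) / 2
    return set(sub.index[keep])


def expression_sets(
    counts: CountMatrix,
    manifest: SampleManifest,
    groups: tuple[str, ...],
    fractions: tuple[str, ...] = ("soluble", "pellet"),
) -> dict[tuple[str, str], set[str]]:
    """Expression filter applied to every (group, fraction) cell."""
    return {
        (g, f): expression_filter(counts, manifest, g, f) for g in groups for f in fractions
    }


@dataclass(frozen=True)
class VennSummary:
    cell_counts: dict[tuple[str, str], int]
    union: int


def venn_summary(sets: Mapping[tuple[str, str], set[str]]) -> VennSummary:
    """Cardinality of each (group, fraction) expressed set plus their union."""
    union: set[str] = set()
    for s in sets.values():
        union |= s
    return VennSummary({cell: len(s) for cell, s in sets.items()}, len(union))


def center_ratios(ratios: pd.DataFrame) -> pd.DataFrame:
    """Subtract each protein's mean across subjects (rows end with mean 0)."""
    if ratios.shape[1] < 2:
        raise ValidationError("centering needs >= 2 subjects")
    return ratios.sub(ratios.mean(axis=1), axis=0)
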