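"""Local gene-set over-representation testing.

One-tailed hypergeometric (Fisher) test of term overlap in a hit set
against a background, with the conservative EASE variant (one hit removed
from the term overlap before computing the tail) as the default mode.
The background conventionally defaults to all proteins observed in the
experiment, not the whole annotation universe.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._errors import ValidationError
from .differential import bh_adjust

MODES = ("fisher", "ease")


def fisher_overrepresentation(
    hits: Iterable[str],
    background: Iterable[str],
    annot: Mapping[str, set[str]],
    mode: str = "ease",
    min_hits: int = 1,
) -> pd.DataFrame:
    """Per-term over-representation p values for a hit set.

    For each term the p value is the hypergeometric upper tail of drawing
    at least ``hits_in_term`` annotated proteins in ``len(hits)`` draws
    from the background. ``mode='ease'`` decrements the observed overlap by
    one (floored at 0) before taking the tail. Terms with overlap below
    ``min_hits`` are skipped; p values are BH-adjusted across tested terms.
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    hit_set = set(hits)
    bg_set = set(background)
    if not hit_set <= bg_set:
        raise ValidationError("hits must be a subset of the background")
    M, N = len(bg_set), len(hit_set)
    rows = []
    for term_id in sorted(annot):
        term_bg = annot[term_id] & bg_set
        a = len(annot[term_id] & hit_set)
        if a < max(min_hits, 1):
            continue
        n = len(term_bg)
        k = a - 1 if mode == "ease" else a
        p = float(hypergeom.sf(max(k, 0) - 1, M, n, N))
        b = N - a  # hits outside term
        c = n - a  # background-only in term
        d = M - N - c
        if b * c > 0:
            odds = (a * d) / (b * c)
        elif a * d > 0:
            odds = np.inf
        else:
            odds = 0.0
        rows.append(
            {
                "term_id": term_id,
                "hits_in_term": a,
                "hits_total": N,
                "background_in_term": n,
                "background_total": M,
                "odds_ratio": odds,
                "p": min(p, 1.0),
                "mode": mode,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "hits_in_term",
            "hits_total",
            "background_in_term",
            "background_total",
            "odds_ratio",
            "p",
            "mode",
        ],
    )
    records["q"] = bh_adjust(records["p"].to_numpy()) if len(records) else []
    return records


def rank_terms(records: pd.DataFrame) -> pd.DataFrame:
    """Stable sort by ascending p, then descending odds ratio, then term id."""
    if records.empty:
        return records.copy()
    return records.sort_values(
        ["p", "odds_ratio", "term_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
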