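"""Data model and tabular I/O for spectral-count insolubility analysis.

The on-disk formats are plain UTF-8 text with a single header row (TSV by
default, CSV supported):

* count matrix   — column 1 = protein id, remaining headers = sample ids,
  body = non-negative integer spectral counts (blank cells read as 0);
* sample manifest — named columns ``sample_id``, ``subject_id``, ``group``,
  ``fraction`` plus optional ``age`` and ``sex``;
* protein metadata — ``protein_id``, optional ``gene_symbol`` and
  ``predicted_mw`` (kDa);
* annotation map  — two columns, ``term_id`` then ``protein_id``, one pair
  per line, for over-representation testing.

Groups are the closed set {control, MCI, AD}; fractions are
{soluble, pellet}. Tokens are matched case-insensitively and canonicalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import FormatError, PairingError, ValidationError

GROUPS = ("control", "MCI", "AD")
FRACTIONS = ("soluble", "pellet")
SEXES = ("F", "M")

_GROUP_CANON = {g.lower(): g for g in GROUPS}
_FRACTION_CANON = {f.lower(): f for f in FRACTIONS}
_SEX_CANON = {s.lower(): s for s in SEXES}

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


def _sep(dialect: str) -> str:
    try:
        return _DIALECT_SEP[dialect]
    except KeyError:  # pragma: no cover - defensive
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


@dataclass(frozen=True)
class SampleRecord:
    """One MS run: a (subject, fraction) cell of the cohort design."""

    sample_id: str
    subject_id: str
    group: str
    fraction: str
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"unknown fraction {self.fraction!r}; expected one of {FRACTIONS}"
            )
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}; expected one of {SEXES}")


@dataclass(frozen=True)
class SampleManifest:
    """Ordered collection of :class:`SampleRecord` with unique sample ids.

    Each (subject_id, fraction) appears at most once, so soluble/pellet
    pairing per subject is derivable.
    """

    records: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        cells = [(r.subject_id, r.fraction) for r in self.records]
        if len(set(cells)) != len(cells):
            dup = sorted({c for c in cells if cells.count(c) > 1})
            raise ValidationError(f"subject/fraction cell(s) appear more than once: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def subset(self, sample_ids: set[str]) -> "SampleManifest":
        return SampleManifest(tuple(r for r in self.records if r.sample_id in sample_ids))

    def samples(self, group: str | None = None, fraction: str | None = None) -> list[str]:
        """Sample ids restricted to a (group, fraction) cell."""
        return [
            r.sample_id
            for r in self.records
            if (group is None or r.group == group)
            and (fraction is None or r.fraction == fraction)
        ]

    def group_of_subject(self) -> dict[str, str]:
        return {r.subject_id: r.group for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "subject_id": [r.subject_id for r in self.records],
                "group": [r.group for r in self.records],
                "fraction": [r.fraction for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleManifest":
        required = {"sample_id", "subject_id", "group", "fraction"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"manifest missing column(s): {sorted(missing)}")
        records = []
        for _, row in frame.iterrows():
            group = _canon(row["group"], _GROUP_CANON, "group")
            fraction = _canon(row["fraction"], _FRACTION_CANON, "fraction")
            age = row.get("age")
            age = None if age is None or pd.isna(age) else float(age)
            sex = row.get("sex")
            sex = None if sex is None or pd.isna(sex) else _canon(sex, _SEX_CANON, "sex")
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    subject_id=str(row["subject_id"]),
                    group=group,
                    fraction=fraction,
                    age=age,
                    sex=sex,
                )
            )
        return cls(tuple(records))


def _canon(token: object, table: Mapping[str, str], what: str) -> str:
    key = str(token).strip().lower()
    if key not in table:
        raise ValidationError(f"unknown {what} token {token!r}; expected one of {sorted(set(table.values()))}")
    return table[key]


@dataclass(frozen=True)
class CountMatrix:
    """Integer spectral counts, proteins (rows) x samples (columns)."""

    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate protein id(s): {dup}")
        if df.columns.has_duplicates:
            dup = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample id(s): {dup}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if arr.size and (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        # canonical axis labels so write -> read round-trips exactly
        object.__setattr__(self, "counts", df.rename_axis(index="protein_id", columns=None))

    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, sample_ids])


@dataclass(frozen=True)
class ProteinMeta:
    """Optional per-protein annotation: gene symbol, predicted MW (kDa)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "protein_id" not in self.frame.columns:
            raise FormatError("protein metadata requires a protein_id column")
        if self.frame["protein_id"].duplicated().any():
            raise ValidationError("duplicate protein_id in metadata")
        if "predicted_mw" in self.frame.columns:
            mw = self.frame["predicted_mw"].dropna()
            if ((mw <= 0) | ~np.isfinite(mw)).any():
                raise ValidationError("predicted_mw must be strictly positive and finite")

    def predicted_mw(self) -> dict[str, float]:
        if "predicted_mw" not in self.frame.columns:
            return {}
        sub = self.frame.dropna(subset=["predicted_mw"])
        return dict(zip(sub["protein_id"], sub["predicted_mw"].astype(float)))


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a protein x sample count table; blank cells become 0.

    Undetected proteins are absences, not missing data, so blanks are
    zero-filled. Non-numeric or negative cells raise :class:`FormatError`
    naming the offending row and column.
    """
    raw = pd.read_csv(
        path, sep=_sep(dialect), index_col=0, dtype=str, keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValidationError(f"duplicate protein id(s) in {path}: {dup}")
    cleaned = raw.apply(lambda s: s.str.strip()).replace("", "0")
    numeric = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        rid, col = _first_true_cell(bad)
        raise FormatError(
            f"non-numeric count {raw.loc[rid, col]!r} at protein {rid!r}, sample {col!r}"
        )
    neg = numeric < 0
    if neg.to_numpy().any():
        rid, col = _first_true_cell(neg)
        raise FormatError(
            f"negative count {numeric.loc[rid, col]} at protein {rid!r}, sample {col!r}"
        )
    frac = numeric != numeric.round()
    if frac.to_numpy().any():
        rid, col = _first_true_cell(frac)
        raise FormatError(
            f"non-integer count {numeric.loc[rid, col]} at protein {rid!r}, sample {col!r}"
        )
    return CountMatrix(numeric.astype(np.int64))


def _first_true_cell(mask: pd.DataFrame) -> tuple[str, str]:
    i, j = np.argwhere(mask.to_numpy())[0]
    return mask.index[i], mask.columns[j]


def write_count_table(matrix: CountMatrix, path: str | Path, dialect: str = "tsv") -> None:
    matrix.counts.to_csv(path, sep=_sep(dialect), index_label="protein_id")


def read_manifest(path: str | Path, dialect: str = "tsv") -> SampleManifest:
    frame = pd.read_csv(path, sep=_sep(dialect))
    return SampleManifest.from_frame(frame)


def write_manifest(manifest: SampleManifest, path: str | Path, dialect: str = "tsv") -> None:
    manifest.to_frame().to_csv(path, sep=_sep(dialect), index=False)


def read_protein_meta(path: str | Path, dialect: str = "tsv") -> ProteinMeta:
    return ProteinMeta(pd.read_csv(path, sep=_sep(dialect)))


def write_protein_meta(meta: ProteinMeta, path: str | Path, dialect: str = "tsv") -> None:
    meta.frame.to_csv(path, sep=_sep(dialect), index=False)


def read_annotation_map(path: str | Path, dialect: str = "tsv") -> dict[str, set[str]]:
    """Two-column term_id -> protein_id table into a term -> set map."""
    frame = pd.read_csv(path, sep=_sep(dialect), header=None, names=["term_id", "protein_id"], dtype=str, comment="#")
    annot: dict[str, set[str]] = {}
    for term, prot in zip(frame["term_id"], frame["protein_id"]):
        annot.setdefault(term, set()).add(prot)
    return annot


# ---------------------------------------------------------------------------
# pairing


def validate_pairing(manifest: SampleManifest, counts: CountMatrix) -> dict[str, tuple[str, str]]:
    """Derive the subject -> (soluble sample, pellet sample) map.

    Only subjects with both fractions present in ``counts`` are returned;
    dropped subjects are reported through ``warnings``. Samples present in
    the counts but absent from the manifest are an inconsistency and raise.
    Zero complete pairs is a hard error — nothing downstream can run.
    """
    manifest_ids = set(manifest.sample_ids)
    stray = [s for s in counts.sample_ids if s not in manifest_ids]
    if stray:
        raise ValidationError(f"count matrix sample(s) missing from manifest: {stray}")
    present = set(counts.sample_ids)
    by_subject: dict[str, dict[str, str]] = {}
    for rec in manifest:
        if rec.sample_id in present:
            by_subject.setdefault(rec.subject_id, {})[rec.fraction] = rec.sample_id
    pairs = {
        subj: (frs["soluble"], frs["pellet"])
        for subj, frs in by_subject.items()
        if "soluble" in frs and "pellet" in frs
    }
    dropped = sorted(set(by_subject) - set(pairs))
    if dropped:
        warnings.warn(f"subject(s) without both fractions dropped: {dropped}", stacklevel=2)
    if not pairs:
        raise PairingError("no subject has both a soluble and a pellet sample")
    return pairs
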