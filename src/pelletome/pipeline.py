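"""End-to-end pipeline: normalize -> ratio -> center -> PCA/outlier -> test.

``run_pipeline`` wires the stages in a fixed order — pseudo-count log2 and
quantile normalization, per-subject insolubility ratios, per-protein
centering, PCA with robust outlier exclusion, the two differential
rankings, BH adjustment and significance calling, optional
over-representation of the significant set — and writes every output as
TSV next to a JSON run manifest recording package/library versions, a
config hash, and the seed. Analysis stages are deterministic; the seed
only matters for simulation inputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn
import yaml

from . import __version__
from .differential import SignificanceConfig, call_significant, method1_rank, method2_rank
from .enrichment import fisher_overrepresentation, rank_terms
from .insolubility import (
    VennSummary,
    center_ratios,
    expression_sets,
    insolubility_ratio,
    venn_summary,
)
from .io import (
    CountMatrix,
    SampleManifest,
    read_annotation_map,
    read_count_table,
    read_manifest,
    validate_pairing,
)
from .normalize import NormalizationConfig, normalize_counts
from .pca import OutlierReport, PCAResult, exclude_subjects, flag_outliers, pca_on_ratios


@dataclass(frozen=True)
class OutlierConfig:
    enabled: bool = True
    k: float = 3.0
    n_pcs: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    counts_path: str
    manifest_path: str
    contrast: tuple[str, str] = ("AD", "control")  # (disease, control)
    annot_path: str | None = None
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    outliers: OutlierConfig = field(default_factory=OutlierConfig)
    enrichment_mode: str = "ease"
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (
            ("normalization", NormalizationConfig),
            ("significance", SignificanceConfig),
            ("outliers", OutlierConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)


@dataclass
class PipelineResult:
    normalized: pd.DataFrame
    ratios: pd.DataFrame
    centered: pd.DataFrame
    pca: PCAResult
    outliers: list[OutlierReport]
    method1: pd.DataFrame
    method2: pd.DataFrame
    significant: list[str]
    venn: VennSummary
    enrichment: pd.DataFrame | None


def run_pipeline(
    config: PipelineConfig,
    counts: CountMatrix | None = None,
    manifest: SampleManifest | None = None,
) -> PipelineResult:
    """Execute the full differential-insolubility analysis.

    ``counts``/``manifest`` may be passed in memory; otherwise they are read
    from the configured paths. Outlier exclusion (when enabled) is applied
    before any differential testing. When ``out_dir`` is set every table is
    written as TSV plus a run manifest.
    """
    if counts is None:
        counts = read_count_table(config.counts_path)
    if manifest is None:
        manifest = read_manifest(config.manifest_path)
    disease, control = config.contrast

    contrast_samples = [
        s
        for s in counts.sample_ids
        if s in set(manifest.samples(group=disease)) | set(manifest.samples(group=control))
    ]
    counts_c = counts.subset_samples(contrast_samples)

    pairing = validate_pairing(manifest.subset(set(contrast_samples)), counts_c)
    sets = expression_sets(counts_c, manifest, groups=(control, disease))
    venn = venn_summary(sets)

    normalized = normalize_counts(counts_c, config.normalization, manifest)
    ratios = insolubility_ratio(normalized, pairing)
    centered = center_ratios(ratios)

    pca = pca_on_ratios(centered)
    if config.outliers.enabled:
        reports = flag_outliers(pca, k=config.outliers.k, n_pcs=config.outliers.n_pcs)
        ratios = exclude_subjects(ratios, reports, manifest)
    else:
        reports = []
    excluded = {r.subject_id for r in reports if r.flagged}
    kept_subjects = [s for s in ratios.columns]
    kept_samples = [
        sid for subj in kept_subjects for sid in pairing[subj]
    ]
    manifest_kept = manifest.subset(set(kept_samples))

    method1 = call_significant(
        method1_rank(
            counts_c.subset_samples(kept_samples),
            manifest_kept,
            disease=disease,
            control=control,
            pseudo_count=config.normalization.pseudo_count,
        ),
        config.significance,
    )
    method2 = call_significant(
        method2_rank(ratios, manifest, disease=disease, control=control),
        config.significance,
    )
    significant = sorted(method2.loc[method2["significant"], "protein_id"])

    enrichment = None
    if config.annot_path:
        annot = read_annotation_map(config.annot_path)
        background = set(counts_c.protein_ids)
        if significant:
            enrichment = rank_terms(
                fisher_overrepresentation(
                    set(significant), background, annot, mode=config.enrichment_mode
                )
            )
        else:
            enrichment = fisher_overrepresentation(set(), background, annot, mode=config.enrichment_mode)

    result = PipelineResult(
        normalized=normalized,
        ratios=ratios,
        centered=centered,
        pca=pca,
        outliers=reports,
        method1=method1.sort_values(["q_welch", "protein_id"], kind="mergesort").reset_index(drop=True),
        method2=method2.sort_values(["q_welch", "protein_id"], kind="mergesort").reset_index(drop=True),
        significant=significant,
        venn=venn,
        enrichment=enrichment,
    )
    if config.out_dir:
        _write_outputs(config, result, excluded)
    return result


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_outputs(config: PipelineConfig, result: PipelineResult, excluded: set[str]) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.normalized.to_csv(out / "normalized.tsv", sep="\t", index_label="protein_id")
    result.ratios.to_csv(out / "ratios.tsv", sep="\t", index_label="protein_id")
    scores = pd.DataFrame(
        result.pca.scores,
        index=list(result.pca.subject_ids),
        columns=[f"PC{i + 1}" for i in range(result.pca.scores.shape[1])],
    )
    scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="subject_id")
    pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "robust_distance": r.robust_distance,
                "flagged": r.flagged,
                "threshold": r.threshold,
            }
            for r in result.outliers
        ]
    ).to_csv(out / "outliers.tsv", sep="\t", index=False)
    result.method1.to_csv(out / "method1_raw_ratio.tsv", sep="\t", index=False)
    result.method2.to_csv(out / "method2_fraction_normalized.tsv", sep="\t", index=False)
    venn_rows = [
        {"group": g, "fraction": f, "n_expressed": n}
        for (g, f), n in result.venn.cell_counts.items()
    ] + [{"group": "union", "fraction": "all", "n_expressed": result.venn.union}]
    pd.DataFrame(venn_rows).to_csv(out / "venn.tsv", sep="\t", index=False)
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    run_manifest = {
        "package": "pelletome",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "contrast": list(config.contrast),
        "excluded_subjects": sorted(excluded),
        "n_significant": len(result.significant),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2) + "\n")
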