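"""End-to-end stratified analysis: impute -> variance filter -> NB Wald DE
-> rank -> pre-ranked GSEA per stratum, then cross-stratum comparison and
literature impact scoring of the significant pathways.

Every source of randomness is derived from one master seed via stable
per-stage hashes, so each stage is independently reproducible and a rerun
with the same configuration is bit-identical in fixture/synthetic mode.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import P_FLOOR, estimate_size_factors, wald_test, write_de_table
from .errors import ConfigError
from .gsea import (
    StratumComparison,
    build_ranked_list,
    compare_strata,
    gsea_preranked,
    significant_pathways,
    write_enrichment,
)
from .io import (
    CountMatrix,
    GeneSetCollection,
    LiteratureCounts,
    SampleMetadata,
    read_counts,
    read_gmt,
    read_literature_counts,
    read_metadata,
    write_counts,
    write_gmt,
    write_literature_counts,
    write_metadata,
)
from .literature import FixtureProvider, score_pathways, write_impact_table
from .simulate import (
    SimConfig,
    simulate_cohort,
    simulate_gene_sets,
    simulate_literature_corpus,
)
from .varpart import (
    filter_genes,
    impute_pmi,
    partition_variance,
    transform_counts,
    write_variance_fractions,
)

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    """Single configuration object for the whole stratified pipeline.

    Exactly one of file mode (``counts_path`` + ``metadata_path`` +
    ``gmt_path``) or synthetic mode (``synthetic=True``) must be active.
    """

    # file mode
    counts_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None
    universe_gmt_path: str | None = None
    literature_cache: str | None = None
    # synthetic mode
    synthetic: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    sim_n_random_sets: int = 150
    sim_n_signal_sets: int = 10
    sim_set_size_range: tuple[int, int] = (15, 100)
    sim_universe_size: int = 1500
    sim_background_r: float = 0.02
    sim_planted_r: float = 0.3
    # stage parameters
    stratify_by: str = "sex"
    min_diagnosis_fraction: float = 0.01
    shrink_dispersion: bool = False
    n_perm: int = 1000
    exponent: float = 1.0
    min_size: int = 15
    max_size: int = 500
    q_threshold: float = 0.05
    n_null: int = 1000
    disease: str = "Alzheimer's disease"
    padj_threshold: float = 0.05
    l2fc_threshold: float = 1.0
    top_k: int = 20
    score_all_pathways: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        file_mode = self.counts_path is not None
        if file_mode == self.synthetic:
            raise ConfigError("exactly one of file mode or synthetic mode must be active")
        if file_mode:
            for name in ("counts_path", "metadata_path", "gmt_path"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigError(f"file mode requires {name}")
                if not Path(value).exists():
                    raise ConfigError(f"{name} does not exist: {value}")
            for name in ("universe_gmt_path", "literature_cache"):
                value = getattr(self, name)
                if value is not None and not Path(value).exists():
                    raise ConfigError(f"{name} does not exist: {value}")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim_raw = raw.pop("sim", None)
        if sim_raw is not None:
            if "strata" in sim_raw:
                sim_raw["strata"] = tuple(tuple(s) for s in sim_raw["strata"])
            for key in (
                "baseline_mean_log", "dispersion_log", "effect_size_log2",
                "age_range", "rin_normal", "pmi_normal",
            ):
                if key in sim_raw:
                    sim_raw[key] = tuple(sim_raw[key])
            raw["sim"] = SimConfig(**sim_raw)
        if "sim_set_size_range" in raw:
            raw["sim_set_size_range"] = tuple(raw["sim_set_size_range"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class StratumResult:
    label: str
    variance_fractions: pd.DataFrame
    retained_genes: list[str]
    de: pd.DataFrame
    volcano: pd.DataFrame
    top_genes: pd.DataFrame
    enrichment: pd.DataFrame


@dataclass
class ReportBundle:
    config: PipelineConfig
    strata: dict[str, StratumResult]
    comparison: StratumComparison | None
    impact: pd.DataFrame | None
    manifest: dict


def make_volcano_table(
    de: pd.DataFrame, padj_threshold: float = 0.05, l2fc_threshold: float = 1.0
) -> pd.DataFrame:
    """Volcano-plot data: L2FC vs -log10 adjusted p with significance class.

    A gene is ``up`` when padj < threshold and L2FC >= +l2fc_threshold,
    ``down`` when padj < threshold and L2FC <= -l2fc_threshold, otherwise
    ``not_significant``.
    """
    padj = de["padj"].to_numpy(dtype=float)
    l2fc = de["log2FC"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(np.clip(padj, P_FLOOR, None))
    sig = np.where(
        (padj < padj_threshold) & (l2fc >= l2fc_threshold),
        "up",
        np.where(
            (padj < padj_threshold) & (l2fc <= -l2fc_threshold),
            "down",
            "not_significant",
        ),
    )
    sig = np.where(np.isfinite(padj) & np.isfinite(l2fc), sig, "not_significant")
    return pd.DataFrame(
        {"log2FC": l2fc, "neg_log10_padj": neg_log10, "significance": sig},
        index=de.index,
    )


def top_genes(de: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k genes by |-log10(adjusted p) * L2FC|, regardless of direction."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    usable = de.dropna(subset=["padj", "log2FC"])
    padj = np.clip(usable["padj"].to_numpy(dtype=float), P_FLOOR, None)
    rank_value = -np.log10(padj) * usable["log2FC"].to_numpy(dtype=float)
    table = usable.assign(rank_value=rank_value)
    order = sorted(
        range(len(table)),
        key=lambda i: (-abs(rank_value[i]), str(table.index[i])),
    )
    return table.iloc[order[:k]][["log2FC", "padj", "rank_value"]]


def _run_stratum(
    label: str,
    counts: CountMatrix,
    metadata: SampleMetadata,
    collection: GeneSetCollection,
    config: PipelineConfig,
) -> StratumResult | None:
    dx = metadata.table["diagnosis"]
    n_ctl, n_ad = int((dx == "CTL").sum()), int((dx == "AD").sum())
    if n_ctl < 2 or n_ad < 2:
        logger.warning(
            "stratum %r skipped: %d CTL / %d AD samples (need >= 2 each)",
            label, n_ctl, n_ad,
        )
        return None
    t0 = time.time()
    metadata = impute_pmi(metadata)
    size_factors = estimate_size_factors(counts)
    expr = transform_counts(counts, size_factors)
    fractions = partition_variance(expr, metadata)
    retained = filter_genes(fractions, config.min_diagnosis_fraction)
    logger.info(
        "stratum %r: variance filter retained %d / %d genes",
        label, len(retained), len(counts.gene_ids),
    )
    filtered = CountMatrix(counts.counts.loc[retained])
    de = wald_test(
        filtered,
        metadata,
        size_factors=size_factors,
        shrink_dispersion=config.shrink_dispersion,
    )
    n_flagged = int((de["flag"] != "").sum())
    if n_flagged:
        logger.info("stratum %r: %d gene fits flagged", label, n_flagged)
    ranked = build_ranked_list(de)
    enrichment = gsea_preranked(
        ranked,
        collection,
        n_perm=config.n_perm,
        seed=stage_seed(config.seed, "gsea"),
        exponent=config.exponent,
        min_size=config.min_size,
        max_size=config.max_size,
    )
    logger.info(
        "stratum %r: %d pathways tested, %d significant (q < %g) [%.1fs]",
        label,
        len(enrichment),
        int((enrichment["qval"] < config.q_threshold).sum()) if len(enrichment) else 0,
        config.q_threshold,
        time.time() - t0,
    )
    return StratumResult(
        label=label,
        variance_fractions=fractions,
        retained_genes=retained,
        de=de,
        volcano=make_volcano_table(de, config.padj_threshold, config.l2fc_threshold),
        top_genes=top_genes(de, config.top_k),
        enrichment=enrichment,
    )


def _synthetic_inputs(
    config: PipelineConfig,
) -> tuple[CountMatrix, SampleMetadata, GeneSetCollection, list[str], LiteratureCounts]:
    sim = dataclasses.replace(config.sim, seed=stage_seed(config.seed, "simulate"))
    counts, metadata, truth = simulate_cohort(sim)
    planted: dict[str, list[str]] = {}
    for stratum, effects in truth.de_effects.items():
        up = [g for g, f in effects.items() if f > 0]
        down = [g for g, f in effects.items() if f < 0]
        if len(up) >= config.min_size:
            planted[f"PLANTED_{stratum.upper()}_UP"] = up
        if len(down) >= config.min_size:
            planted[f"PLANTED_{stratum.upper()}_DOWN"] = down
    # real pathway collections spread a perturbation across many partially
    # overlapping sets; emulate that with sets mixing planted and background
    # genes at varying proportions
    sig_rng = np.random.default_rng(stage_seed(config.seed, "signal_sets"))
    all_planted = {g for effects in truth.de_effects.values() for g in effects}
    background = [g for g in counts.gene_ids if g not in all_planted]
    lo, hi = config.sim_set_size_range
    for stratum, effects in truth.de_effects.items():
        for direction, sign in (("UP", 1.0), ("DOWN", -1.0)):
            pool = [g for g, f in effects.items() if np.sign(f) == sign]
            if len(pool) < max(config.min_size // 2, 2):
                continue
            for i in range(config.sim_n_signal_sets):
                size = int(sig_rng.integers(lo, hi + 1))
                frac = sig_rng.uniform(0.3, 0.8)
                n_signal = min(int(round(frac * size)), len(pool))
                signal = sig_rng.choice(pool, size=n_signal, replace=False)
                filler = sig_rng.choice(
                    background, size=size - n_signal, replace=False
                )
                planted[f"SIGNAL_{stratum.upper()}_{direction}_{i:02d}"] = (
                    list(signal) + list(filler)
                )
    collection = simulate_gene_sets(
        counts.gene_ids,
        n_sets=config.sim_n_random_sets,
        size_range=config.sim_set_size_range,
        planted=planted,
        seed=stage_seed(config.seed, "gene_sets"),
    )
    universe = [f"NULL_PW_{i:05d}" for i in range(config.sim_universe_size)]
    labels = universe + collection.names
    r_true = {lab: config.sim_background_r for lab in labels}
    for name in planted:
        r_true[name] = config.sim_planted_r
    corpus = simulate_literature_corpus(
        labels, r_true, seed=stage_seed(config.seed, "literature")
    )
    return counts, metadata, collection, universe, corpus


def run_stratified_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full stratified analysis and (optionally) write a ReportBundle."""
    if config.synthetic:
        counts, metadata, collection, universe, corpus = _synthetic_inputs(config)
        provider = FixtureProvider(corpus)
    else:
        counts = read_counts(config.counts_path)
        metadata = read_metadata(config.metadata_path).aligned_to(counts)
        collection = read_gmt(config.gmt_path)
        universe, provider, corpus = [], None, None
        if config.universe_gmt_path is not None:
            universe = read_gmt(config.universe_gmt_path).names
        if config.literature_cache is not None:
            corpus = read_literature_counts(config.literature_cache)
            provider = FixtureProvider(corpus)

    non_pmi = metadata.table[["sex", "diagnosis", "Age", "RIN"]]
    if non_pmi.isna().any().any():
        raise ConfigError(
            "missing metadata outside PMI is not imputable; fix the sample table"
        )

    strata_labels = list(dict.fromkeys(metadata.table[config.stratify_by]))
    results: dict[str, StratumResult] = {}
    for label in strata_labels:
        sample_ids = list(
            metadata.table.index[metadata.table[config.stratify_by] == label]
        )
        res = _run_stratum(
            label,
            counts.subset_samples(sample_ids),
            metadata.subset(sample_ids),
            collection,
            config,
        )
        if res is not None:
            results[label] = res

    comparison = None
    if len(results) == 2:
        (label_a, res_a), (label_b, res_b) = results.items()
        comparison = compare_strata(
            res_a.enrichment,
            res_b.enrichment,
            q_threshold=config.q_threshold,
            label_a=label_a,
            label_b=label_b,
            strict=False,
        )
    elif len(results) > 2:
        logger.warning("more than two strata; cross-stratum comparison skipped")

    impact = None
    if provider is not None and len(universe) >= config.n_null:
        if config.score_all_pathways:
            to_score = sorted(
                set().union(*(set(r.enrichment.index) for r in results.values()))
            ) if results else []
        else:
            to_score = sorted(
                set().union(
                    *(
                        significant_pathways(r.enrichment, d, config.q_threshold)
                        for r in results.values()
                        for d in ("up", "down")
                    )
                )
            ) if results else []
        scorable = [p for p in to_score if not config.synthetic or p in corpus]
        impact = score_pathways(
            scorable,
            universe,
            provider,
            n_null=config.n_null,
            seed=stage_seed(config.seed, "impact"),
        )
    elif provider is not None:
        logger.warning(
            "pathway universe (%d) smaller than n_null (%d); impact scoring skipped",
            len(universe), config.n_null,
        )

    manifest = {
        "package_version": __version__,
        "config": _jsonable(config.to_dict()),
        "stage_seeds": {
            stage: stage_seed(config.seed, stage)
            for stage in ["simulate", "gene_sets", "literature", "impact", "gsea"]
        },
        "strata_run": list(results),
        "gene_counts": {
            label: {
                "input": len(counts.gene_ids),
                "retained_after_variance_filter": len(r.retained_genes),
                "flagged_fits": int((r.de["flag"] != "").sum()),
            }
            for label, r in results.items()
        },
    }
    bundle = ReportBundle(
        config=config, strata=results, comparison=comparison,
        impact=impact, manifest=manifest,
    )
    if config.outdir is not None:
        write_bundle(bundle, Path(config.outdir))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_bundle(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for label, res in bundle.strata.items():
        sub = outdir / label
        sub.mkdir(exist_ok=True)
        write_variance_fractions(res.variance_fractions, sub / "variance_fractions.tsv")
        write_de_table(res.de, sub / "de.tsv")
        res.volcano.to_csv(sub / "volcano.tsv", sep="\t", index_label="gene_id")
        res.top_genes.to_csv(sub / "top_genes.tsv", sep="\t", index_label="gene_id")
        write_enrichment(res.enrichment, sub / "enrichment.tsv")
    if bundle.comparison is not None:
        bundle.comparison.counts().to_csv(outdir / "comparison.tsv", sep="\t")
        with open(outdir / "comparison.json", "w", encoding="utf-8") as fh:
            json.dump(bundle.comparison.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    if bundle.impact is not None:
        write_impact_table(bundle.impact, outdir / "impact.tsv")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(bundle.manifest), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_synthetic_inputs(config: PipelineConfig, outdir: Path) -> None:
    """Materialize the synthetic inputs (counts/metadata/GMT/corpus) to disk."""
    counts, metadata, collection, universe, corpus = _synthetic_inputs(config)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(counts, outdir / "counts.tsv")
    write_metadata(metadata, outdir / "metadata.tsv")
    write_gmt(collection, outdir / "gene_sets.gmt")
    write_literature_counts(corpus, outdir / "literature_counts.json")
    with open(outdir / "universe.txt", "w", encoding="utf-8") as fh:
        fh.write("\n".join(universe) + "\n")
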