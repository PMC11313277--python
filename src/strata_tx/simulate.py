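"""Synthetic cohorts, gene-set collections and literature corpora.

The generator emulates a two-stratum post-mortem brain RNA-seq cohort:
negative-binomial counts (gamma-Poisson mixture, var = mu + alpha*mu^2),
per-sample library-size multipliers, three nuisance covariates (Age, RIN,
PMI) entering the log-mean linearly, and a diagnosis effect planted on a
configurable fraction of genes independently in each stratum.  The default
stratum layout reproduces the study design this package targets: female
36 CTL / 28 AD and male 39 CTL / 16 AD (119 subjects).

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .io import CountMatrix, GeneSet, GeneSetCollection, LiteratureCounts, SampleMetadata

DEFAULT_STRATA: tuple[tuple[str, int, int], ...] = (
    ("female", 36, 28),
    ("male", 39, 16),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    ``baseline_mean_log`` and ``dispersion_log`` are (location, scale) of
    normal distributions on the natural-log scale for the per-gene mean
    count and NB dispersion alpha.  ``effect_size_log2`` is (location,
    scale) of the *magnitude* of planted log2 fold changes (sign is a fair
    coin).  ``covariate_effect_scale`` is the standard deviation of the
    per-gene coefficients on the z-scored covariates (natural-log scale).
    """

    n_genes: int = 2000
    strata: tuple[tuple[str, int, int], ...] = DEFAULT_STRATA
    baseline_mean_log: tuple[float, float] = (4.0, 1.2)
    dispersion_log: tuple[float, float] = (float(np.log(0.1)), 0.5)
    de_fraction_per_stratum: float = 0.1
    effect_size_log2: tuple[float, float] = (1.0, 0.25)
    covariate_effect_scale: float = 0.1
    libsize_log_sd: float = 0.25
    pmi_missing_rate: float = 0.1
    age_range: tuple[float, float] = (60.0, 95.0)
    rin_normal: tuple[float, float, float, float] = (7.5, 1.0, 2.0, 10.0)
    pmi_normal: tuple[float, float, float, float] = (10.0, 5.0, 0.5, 40.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not self.strata:
            raise ConfigError("at least one stratum is required")
        for label, n_ctl, n_ad in self.strata:
            if n_ctl < 2 or n_ad < 2:
                raise ConfigError(
                    f"stratum {label!r} needs >= 2 samples per diagnosis group"
                )
        for name, value in (
            ("de_fraction_per_stratum", self.de_fraction_per_stratum),
            ("pmi_missing_rate", self.pmi_missing_rate),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.covariate_effect_scale < 0 or self.libsize_log_sd < 0:
            raise ConfigError("scales must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for downstream oracles.

    ``de_effects`` maps stratum label -> {gene id: true log2 fold change};
    ``size_factors`` are the true per-sample library-size multipliers.
    """

    de_effects: Mapping[str, Mapping[str, float]]
    size_factors: pd.Series

    def de_genes(self, stratum: str) -> set[str]:
        return set(self.de_effects.get(stratum, {}))


def _truncated_normal(
    rng: np.random.Generator, loc: float, scale: float, lo: float, hi: float, size: int
) -> np.ndarray:
    a, b = (lo - loc) / scale, (hi - loc) / scale
    dist = stats.truncnorm(a, b, loc=loc, scale=scale)
    return dist.ppf(rng.uniform(size=size))


def _nb_counts(
    rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + alpha*mu^2 (Poisson when alpha=0)."""
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_mask = alpha <= 0
    if np.any(poisson_mask):
        out[poisson_mask] = rng.poisson(mu[poisson_mask])
    if np.any(~poisson_mask):
        a = alpha[~poisson_mask]
        lam = rng.gamma(shape=1.0 / a, scale=mu[~poisson_mask] * a)
        out[~poisson_mask] = rng.poisson(lam)
    return out


def simulate_cohort(config: SimConfig) -> tuple[CountMatrix, SampleMetadata, GroundTruth]:
    """Simulate counts, metadata, and the planted ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    base_log_mean = rng.normal(*config.baseline_mean_log, size=config.n_genes)
    alpha = np.exp(rng.normal(*config.dispersion_log, size=config.n_genes))
    # per-gene nuisance coefficients on z-scored Age / RIN / PMI
    covar_beta = rng.normal(0.0, config.covariate_effect_scale, size=(config.n_genes, 3))

    sample_ids: list[str] = []
    rows: list[dict] = []
    count_columns: list[np.ndarray] = []
    de_effects: dict[str, dict[str, float]] = {}
    true_sf: list[float] = []

    for label, n_ctl, n_ad in config.strata:
        n = n_ctl + n_ad
        dx = np.array([0] * n_ctl + [1] * n_ad)
        age = rng.uniform(*config.age_range, size=n)
        rin = _truncated_normal(rng, *config.rin_normal, size=n)
        pmi = _truncated_normal(rng, *config.pmi_normal, size=n)
        pmi_missing = rng.uniform(size=n) < config.pmi_missing_rate
        log_sf = rng.normal(0.0, config.libsize_log_sd, size=n)

        n_de = int(round(config.de_fraction_per_stratum * config.n_genes))
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
        magnitude = rng.normal(*config.effect_size_log2, size=n_de)
        sign = rng.choice([-1.0, 1.0], size=n_de)
        l2fc = magnitude * sign
        de_effects[label] = {genes[i]: float(f) for i, f in zip(de_idx, l2fc)}

        def zscore(x: np.ndarray) -> np.ndarray:
            s = x.std()
            return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

        covars = np.column_stack([zscore(age), zscore(rin), zscore(pmi)])
        log_mu = base_log_mean[:, None] + covar_beta @ covars.T  # genes x samples
        effect_full = np.zeros((config.n_genes, n))
        effect_full[de_idx, :] = np.outer(l2fc * np.log(2.0), dx)
        log_mu = log_mu + effect_full + log_sf[None, :]
        mu = np.exp(log_mu)
        counts = _nb_counts(rng, mu, np.broadcast_to(alpha[:, None], mu.shape).copy())
        count_columns.append(counts)

        prefix = label[0].upper()
        for j in range(n):
            sid = f"{prefix}{len(sample_ids) + 1:04d}"
            sample_ids.append(sid)
            rows.append(
                {
                    "sample_id": sid,
                    "sex": label,
                    "diagnosis": "AD" if dx[j] else "CTL",
                    "Age": round(float(age[j]), 1),
                    "RIN": round(float(rin[j]), 2),
                    "PMI": np.nan if pmi_missing[j] else round(float(pmi[j]), 2),
                }
            )
        true_sf.extend(np.exp(log_sf).tolist())

    counts_df = pd.DataFrame(
        np.hstack(count_columns), index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )
    meta_df = pd.DataFrame(rows).set_index("sample_id")
    truth = GroundTruth(
        de_effects=de_effects,
        size_factors=pd.Series(true_sf, index=sample_ids, name="size_factor"),
    )
    return CountMatrix(counts_df), SampleMetadata(meta_df), truth


def simulate_gene_sets(
    gene_universe: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int],
    planted: Mapping[str, Sequence[str]] | None = None,
    seed: int = 0,
) -> GeneSetCollection:
    """Random same-universe gene sets plus caller-planted sets.

    Random sets are named ``RANDOM_SET_0001`` ... and drawn without
    replacement from the universe with sizes uniform over ``size_range``.
    """
    planted = dict(planted or {})
    universe = list(gene_universe)
    universe_set = set(universe)
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ConfigError(f"size_range {size_range} outside [1, {len(universe)}]")
    for name, members in planted.items():
        extra = set(members) - universe_set
        if extra:
            raise ValidationError(
                f"planted set {name!r} has genes outside the universe: {sorted(extra)[:5]}"
            )
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    for name, members in planted.items():
        sets.append(GeneSet(name, "planted", tuple(dict.fromkeys(members))))
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets.append(
            GeneSet(
                f"RANDOM_SET_{i + 1:04d}",
                "random",
                tuple(universe[j] for j in sorted(members)),
            )
        )
    return GeneSetCollection(tuple(sets))


def simulate_literature_corpus(
    pathway_labels: Sequence[str],
    r_true: Mapping[str, float],
    total_counts_log: tuple[float, float] = (float(np.log(500.0)), 1.0),
    seed: int = 0,
) -> LiteratureCounts:
    """Synthetic bibliographic corpus: per label, a log-normal total mention
    count and a binomial co-mention count with success probability r_true."""
    for label in pathway_labels:
        r = r_true.get(label, 0.0)
        if not 0.0 <= r <= 1.0:
            raise ValidationError(f"r_true for {label!r} must lie in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    counts: dict[str, tuple[int, int]] = {}
    for label in pathway_labels:
        total = int(np.round(np.exp(rng.normal(*total_counts_log))))
        total = max(total, 0)
        co = int(rng.binomial(total, r_true.get(label, 0.0))) if total > 0 else 0
        counts[label] = (total, co)
    return LiteratureCounts(counts)
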