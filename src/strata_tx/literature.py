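"""Literature-association impact scoring for pathways.

For a pathway label, the relatedness proportion r is the number of
documents co-mentioning the pathway and the disease divided by the number
of documents mentioning the pathway at all.  The Impact Z-score positions
a pathway's r against a null distribution built from randomly sampled
pathway labels (default 1000) drawn from a large pathway universe and
scored the same way: Z = (r - mean(null)) / sd(null).  High positive Z
means the pathway is already strongly tied to the disease literature;
Z near zero means little prior association.

Counts come from a pluggable :class:`CountProvider`: a deterministic
fixture backed by a :class:`LiteratureCounts` cache (used by all tests),
or a live NCBI E-utilities client (optional, rate-limited, cached).
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import LiteratureCounts, read_literature_counts, write_literature_counts

logger = logging.getLogger(__name__)

DEFAULT_DISEASE = "Alzheimer's disease"


class CountProvider(Protocol):
    """Contract: document counts for a pathway label, alone and with the disease."""

    def counts(self, label: str) -> tuple[int, int]:
        """Return (total mentions, co-mentions with the disease)."""
        ...


def build_query(pathway_label: str, disease: str | None = None) -> str:
    """Normalize a pathway label into a bibliographic query string.

    Underscores and hyphens become spaces, whitespace is collapsed and the
    term lower-cased; multi-word labels are wrapped as an exact phrase.
    With ``disease`` given, the co-mention form ``<pathway> AND <disease>``
    is returned.
    """
    normalized = re.sub(r"[\s_\-]+", " ", pathway_label).strip().lower()
    if not normalized:
        raise ValidationError(f"pathway label {pathway_label!r} is empty after normalization")
    term = f'"{normalized}"' if " " in normalized else normalized
    if disease is None:
        return term
    disease_norm = re.sub(r"\s+", " ", disease).strip()
    if not disease_norm:
        raise ValidationError("disease term is empty")
    disease_term = f'"{disease_norm}"' if " " in disease_norm else disease_norm
    return f"{term} AND {disease_term}"


def relatedness_proportion(co_count: int, total_count: int) -> float:
    """co-mentions / total mentions; 0 by convention when the total is 0."""
    if co_count < 0 or total_count < 0:
        raise ValidationError("counts must be non-negative")
    if co_count > total_count:
        raise ValidationError(
            f"co-mention count {co_count} exceeds total count {total_count}"
        )
    if total_count == 0:
        logger.warning("zero total mentions; relatedness set to 0 by convention")
        return 0.0
    return co_count / total_count


@dataclass(frozen=True)
class ImpactScore:
    pathway: str
    r: float
    null_mean: float
    null_sd: float
    z: float
    n_null: int
    total: int
    co_mentions: int
    zero_total: bool


class FixtureProvider:
    """Deterministic provider backed by a LiteratureCounts mapping."""

    def __init__(self, counts: LiteratureCounts):
        self._counts = counts

    def counts(self, label: str) -> tuple[int, int]:
        if label not in self._counts:
            raise KeyError(f"no literature counts for {label!r}")
        return self._counts[label]


class CachingProvider:
    """Wraps another provider with a JSON-file cache so repeated runs
    issue no duplicate queries."""

    def __init__(self, inner: CountProvider, cache_path: str | Path):
        self._inner = inner
        self._path = Path(cache_path)
        self._cache: dict[str, tuple[int, int]] = {}
        if self._path.exists():
            self._cache = dict(read_literature_counts(self._path).counts)

    def counts(self, label: str) -> tuple[int, int]:
        if label not in self._cache:
            self._cache[label] = self._inner.counts(label)
            write_literature_counts(LiteratureCounts(dict(self._cache)), self._path)
        return self._cache[label]


class EntrezProvider:
    """Live PubMed count provider via NCBI E-utilities esearch.

    Optional: requires biopython and network access.  Queries are retried
    with exponential backoff; a persistent failure raises rather than
    fabricating counts.
    """

    def __init__(
        self,
        email: str,
        disease: str = DEFAULT_DISEASE,
        api_key: str | None = None,
        max_retries: int = 3,
        delay: float = 0.4,
    ):
        from Bio import Entrez  # deferred: live use only

        self._entrez = Entrez
        self._entrez.email = email
        if api_key:
            self._entrez.api_key = api_key
        self.disease = disease
        self.max_retries = max_retries
        self.delay = delay

    def _count(self, query: str) -> int:
        last: Exception | None = None
        for attempt in range(self.max_retries):
            try:
                time.sleep(self.delay * (2**attempt if attempt else 0))
                handle = self._entrez.esearch(db="pubmed", term=query, rettype="count")
                record = self._entrez.read(handle)
                handle.close()
                return int(record["Count"])
            except Exception as exc:  # network / service errors
                last = exc
                logger.warning("esearch failed (attempt %d): %s", attempt + 1, exc)
        raise RuntimeError(f"esearch failed after {self.max_retries} attempts") from last

    def counts(self, label: str) -> tuple[int, int]:
        total = self._count(build_query(label))
        co = self._count(build_query(label, self.disease)) if total > 0 else 0
        return total, min(co, total)


def sample_null(
    universe: Sequence[str],
    n_null: int,
    provider: CountProvider,
    seed: int = 0,
) -> np.ndarray:
    """r values for ``n_null`` labels sampled without replacement from the
    pathway universe."""
    labels = list(universe)
    if len(set(labels)) != len(labels):
        raise ValidationError("pathway universe labels must be unique")
    if len(labels) < n_null:
        raise ValidationError(
            f"universe of {len(labels)} labels is smaller than n_null={n_null}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(labels), size=n_null, replace=False)
    values = np.empty(n_null)
    n_zero = 0
    for i, j in enumerate(chosen):
        total, co = provider.counts(labels[j])
        if total == 0:
            n_zero += 1
        values[i] = relatedness_proportion(co, total)
    if n_zero:
        logger.info("null sample: %d/%d labels had zero total mentions", n_zero, n_null)
    return values


def impact_z(
    r: float,
    null_values: Sequence[float],
    pathway: str = "",
    total: int = 0,
    co_mentions: int = 0,
    zero_total: bool = False,
) -> ImpactScore:
    """Z-score of r against the null sample (sample sd, n-1 denominator)."""
    null = np.asarray(null_values, dtype=float)
    if len(null) < 2:
        raise ValidationError("need >= 2 null values")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd <= 1e-15:
        raise ValidationError(
            "null sample has zero standard deviation; use a larger or more varied universe"
        )
    return ImpactScore(
        pathway=pathway,
        r=r,
        null_mean=mean,
        null_sd=sd,
        z=(r - mean) / sd,
        n_null=len(null),
        total=total,
        co_mentions=co_mentions,
        zero_total=zero_total,
    )


def score_pathways(
    labels: Sequence[str],
    universe: Sequence[str],
    provider: CountProvider,
    n_null: int = 1000,
    seed: int = 0,
    cache_path: str | Path | None = None,
) -> pd.DataFrame:
    """Impact Z-scores for a list of pathway labels against one shared null.

    The null sample is drawn once (single seed) and reused for every
    label.  With ``cache_path`` set, all provider counts go through a JSON
    cache.  Labels the provider cannot score are reported with missing
    values, never fabricated.
    """
    if cache_path is not None:
        provider = CachingProvider(provider, cache_path)
    null = sample_null(universe, n_null, provider, seed=seed)
    rows = []
    for label in labels:
        try:
            total, co = provider.counts(label)
        except Exception as exc:
            logger.warning("label %r left unscored: %s", label, exc)
            rows.append(
                {
                    "pathway": label, "r": np.nan, "null_mean": np.nan,
                    "null_sd": np.nan, "Z": np.nan, "n_null": len(null),
                    "total": np.nan, "co_mentions": np.nan, "zero_total": False,
                }
            )
            continue
        r = relatedness_proportion(co, total)
        score = impact_z(
            r, null, pathway=label, total=total, co_mentions=co, zero_total=total == 0
        )
        rows.append(
            {
                "pathway": score.pathway, "r": score.r, "null_mean": score.null_mean,
                "null_sd": score.null_sd, "Z": score.z, "n_null": score.n_null,
                "total": score.total, "co_mentions": score.co_mentions,
                "zero_total": score.zero_total,
            }
        )
    columns = [
        "pathway", "r", "null_mean", "null_sd", "Z", "n_null",
        "total", "co_mentions", "zero_total",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("pathway")


def write_impact_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="pathway")
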