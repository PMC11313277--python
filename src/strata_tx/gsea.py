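"""Pre-ranked gene-set enrichment with a gene-sampling permutation null.

Genes are ordered by the rank statistic -log10(p) * L2FC (signed, so both
strongly up- and down-regulated genes sit at the extremes).  For each gene
set the classic weighted Kolmogorov-Smirnov running sum is computed: hits
increment by |rank|^exponent normalized over the set's hits, misses
decrement by 1/(N - N_hits); the enrichment score (ES) is the extremum of
largest magnitude.  Significance comes from a seeded gene-sampling null:
``n_perm`` random same-size subsets of the ranked universe, with the
normalized ES (NES) defined as ES divided by the mean |null ES| of
matching sign and a +1 pseudocount permutation p-value.  BH across all
tested pathways gives q-values; pathways are called at q < 0.05 with
direction taken from the NES sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import adjust_bh
from .errors import ValidationError
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ("size", "ES", "NES", "pval", "qval", "direction", "leading_edge")


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending rank value, ties broken lexicographically."""

    genes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.values):
            raise ValidationError("genes and values length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids in ranked list")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("rank values must be finite")

    def __len__(self) -> int:
        return len(self.genes)


def compute_rank_statistic(p: float, l2fc: float) -> float:
    """-log10(p) * L2FC; p must already be floored away from 0."""
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"p-value must lie in (0, 1], got {p}")
    if not np.isfinite(l2fc):
        raise ValidationError("L2FC must be finite")
    return float(-np.log10(p) * l2fc)


def build_ranked_list(
    de: pd.DataFrame, p_column: str = "pvalue", fc_column: str = "log2FC"
) -> RankedList:
    """Rank the DE table by -log10(p) * L2FC, descending.

    Genes with missing p or fold change (flagged fits) are excluded; ties
    are broken by lexicographic gene id so the order is deterministic.
    """
    if de.index.has_duplicates:
        raise ValidationError("duplicate gene ids in DE table")
    usable = de[[p_column, fc_column]].dropna()
    values = -np.log10(usable[p_column].to_numpy()) * usable[fc_column].to_numpy()
    order = sorted(
        range(len(usable)), key=lambda i: (-values[i], str(usable.index[i]))
    )
    return RankedList(
        genes=tuple(str(usable.index[i]) for i in order),
        values=values[order],
    )


def enrichment_score(
    ranked: RankedList, gene_set: Sequence[str], exponent: float = 1.0
) -> tuple[float, int]:
    """Weighted KS enrichment score and the 0-based position of its extremum.

    Hits that carry zero total weight (all ranks exactly 0) fall back to
    equal weighting so the score stays defined.
    """
    hits = np.isin(np.array(ranked.genes), np.array(list(gene_set), dtype=object))
    n = len(ranked)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValidationError("gene set has empty intersection with the ranked universe")
    if n_hits == n:
        raise ValidationError("gene set covers the whole universe; no misses to score")
    weights = np.abs(ranked.values) ** exponent
    hit_weights = np.where(hits, weights, 0.0)
    total = hit_weights.sum()
    if total <= 0:
        hit_weights = hits.astype(float)
        total = float(n_hits)
    step = np.where(hits, hit_weights / total, -1.0 / (n - n_hits))
    running = np.cumsum(step)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def _null_es(
    values: np.ndarray, k: int, n_perm: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """ES for ``n_perm`` random k-subsets of the ranked universe, vectorized.

    The running-sum extremum of a subset is always attained immediately
    before or after a hit, so only the 2k candidate values per permutation
    are evaluated.
    """
    n = len(values)
    weights = np.abs(values) ** exponent
    # sample k positions without replacement per permutation
    keys = rng.random((n_perm, n))
    pos = np.argpartition(keys, k, axis=1)[:, :k]
    pos.sort(axis=1)

    w = weights[pos]
    cumw = np.cumsum(w, axis=1)
    total = cumw[:, -1].copy()
    degenerate = total <= 0
    if np.any(degenerate):
        w[degenerate] = 1.0
        cumw[degenerate] = np.arange(1, k + 1)[None, :]
        total[degenerate] = k
    d = 1.0 / (n - k)
    idx = np.arange(1, k + 1)[None, :]
    after = cumw / total[:, None] - (pos + 1 - idx) * d
    before = (cumw - w) / total[:, None] - (pos - (idx - 1)) * d
    cand = np.concatenate([after, before], axis=1)
    best = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), best]


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation pre-ranked GSEA over a gene-set collection.

    Returns a DataFrame indexed by pathway name with columns size, ES,
    NES, pval, qval, direction, leading_edge.  Pathways whose overlap with
    the ranked universe falls outside [min_size, max_size] are skipped
    with a logged reason; if nothing survives, the result is empty.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    universe = set(ranked.genes)
    gene_array = np.array(ranked.genes)

    tested: list[tuple[str, list[str], int]] = []
    for gene_set in collection:
        members = [g for g in gene_set.members if g in universe]
        k = len(members)
        if k < min_size or k > max_size:
            logger.info(
                "pathway %r skipped: overlap %d outside [%d, %d]",
                gene_set.name, k, min_size, max_size,
            )
            continue
        if k == len(ranked):
            logger.info("pathway %r skipped: covers the whole universe", gene_set.name)
            continue
        tested.append((gene_set.name, members, k))

    if not tested:
        logger.warning("no pathway survived the size filter; empty enrichment result")
        return pd.DataFrame(columns=list(ENRICHMENT_COLUMNS)).rename_axis("pathway")

    # one null ensemble per distinct set size, drawn in sorted-size order so
    # results do not depend on collection order
    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    for k in sorted({k for _, _, k in tested}):
        nulls[k] = _null_es(ranked.values, k, n_perm, exponent, rng)

    rows = []
    for name, members, k in tested:
        es, peak = enrichment_score(ranked, members, exponent)
        null = nulls[k]
        if es >= 0:
            same = null[null > 0]
            exceed = int(np.sum(same >= es))
        else:
            same = null[null < 0]
            exceed = int(np.sum(same <= es))
        pval = (1.0 + exceed) / (1.0 + len(same))
        denom = np.abs(same).mean() if len(same) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        hits_mask = np.isin(gene_array, np.array(members, dtype=object))
        if es >= 0:
            leading = gene_array[: peak + 1][hits_mask[: peak + 1]]
        else:
            leading = gene_array[peak:][hits_mask[peak:]]
        rows.append(
            {
                "pathway": name,
                "size": k,
                "ES": es,
                "NES": nes,
                "pval": pval,
                "direction": "up" if es >= 0 else "down",
                "leading_edge": ";".join(leading),
            }
        )

    result = pd.DataFrame(rows).set_index("pathway")
    result["qval"] = adjust_bh(result["pval"])
    return result[list(ENRICHMENT_COLUMNS)]


@dataclass(frozen=True)
class StratumComparison:
    """Shared / unique significant pathways between two strata, per direction."""

    stratum_a: str
    stratum_b: str
    shared: Mapping[str, tuple[str, ...]]
    unique_a: Mapping[str, tuple[str, ...]]
    unique_b: Mapping[str, tuple[str, ...]]

    def counts(self) -> pd.DataFrame:
        rows = []
        for direction in ("up", "down"):
            rows.append(
                {
                    "direction": direction,
                    "shared": len(self.shared[direction]),
                    f"unique_{self.stratum_a}": len(self.unique_a[direction]),
                    f"unique_{self.stratum_b}": len(self.unique_b[direction]),
                    f"total_{self.stratum_a}": len(self.shared[direction])
                    + len(self.unique_a[direction]),
                    f"total_{self.stratum_b}": len(self.shared[direction])
                    + len(self.unique_b[direction]),
                }
            )
        return pd.DataFrame(rows).set_index("direction")

    def to_dict(self) -> dict:
        return {
            "strata": [self.stratum_a, self.stratum_b],
            "shared": {d: sorted(v) for d, v in self.shared.items()},
            f"unique_{self.stratum_a}": {d: sorted(v) for d, v in self.unique_a.items()},
            f"unique_{self.stratum_b}": {d: sorted(v) for d, v in self.unique_b.items()},
        }


def significant_pathways(
    result: pd.DataFrame, direction: str, q_threshold: float = 0.05
) -> set[str]:
    mask = (result["qval"] < q_threshold) & (result["direction"] == direction)
    return set(result.index[mask])


def compare_strata(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    q_threshold: float = 0.05,
    label_a: str = "A",
    label_b: str = "B",
    strict: bool = True,
) -> StratumComparison:
    """Intersect/difference the significant pathway calls of two strata.

    Both results must come from the same collection; with ``strict`` the
    tested pathway sets must match exactly, while ``strict=False`` allows
    the per-stratum size filter to have dropped different pathways (a set
    not tested in a stratum counts as not significant there).  In either
    case unique + shared = per-stratum total in each direction.
    """
    if strict and set(res_a.index) != set(res_b.index):
        raise ValidationError("enrichment results were not tested against the same collection")
    shared: dict[str, tuple[str, ...]] = {}
    unique_a: dict[str, tuple[str, ...]] = {}
    unique_b: dict[str, tuple[str, ...]] = {}
    for direction in ("up", "down"):
        sig_a = significant_pathways(res_a, direction, q_threshold)
        sig_b = significant_pathways(res_b, direction, q_threshold)
        shared[direction] = tuple(sorted(sig_a & sig_b))
        unique_a[direction] = tuple(sorted(sig_a - sig_b))
        unique_b[direction] = tuple(sorted(sig_b - sig_a))
    return StratumComparison(label_a, label_b, shared, unique_a, unique_b)


def write_enrichment(result: pd.DataFrame, path) -> None:
    result.to_csv(path, sep="\t", index_label="pathway")
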