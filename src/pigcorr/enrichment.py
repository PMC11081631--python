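"""Preranked gene-set enrichment on the |r| ranking.

The running-sum enrichment statistic walks down the ranked gene list:
at a set member ("hit") it rises by that gene's weighted statistic
(|r|^p, p = 1 by default) normalized by the set's total weight, and at a
non-member it falls by 1/(N − N_hit). ES is the signed maximum deviation
of this walk from zero; the leading edge is the members at or before the
extremum (after it, for negative ES).

Significance is assessed against a gene-permutation null: random sets of
the same size drawn from the ranked universe. The p-value conditions on
the sign of the observed ES,

    p = (1 + #{null of same sign with |ES_null| >= |ES|})
        / (1 + #{null of same sign}),

NES = ES / mean(|ES_null| of the same sign), and FDR control is
Benjamini–Hochberg across the tested sets. Significant sets partition by
NES sign; with a |r| ranking, NES > 0 means concentration of the set near
the top of the absolute-correlation ranking ("brightness-correlated" in
the pipeline's output naming) and NES < 0 means depletion from it.

Lineages are analyzed independently and their significant-set lists are
intersected, keeping only pathways enriched in every lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .correlation import RankedGeneList

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ESResult",
    "PermutationResult",
    "read_gmt",
    "write_gmt",
    "enrichment_score",
    "permutation_null",
    "adjust_fdr",
    "run_gsea",
    "partition_by_nes",
    "intersect_lineages",
    "LineageEnrichmentSummary",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise ValueError(f"duplicate gene-set name {gs.name!r}")
        self.sets[gs.name] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB member...)."""
    col = GeneSetCollection()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >=3 tab-separated fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                warnings.warn(
                    f"{path}:{ln}: duplicate members in set {name!r} deduplicated",
                    stacklevel=2,
                )
            col.add(GeneSet(name=name, description=desc, genes=tuple(uniq)))
    return col


def write_gmt(collection: GeneSetCollection, path: str) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    hit_positions: np.ndarray


def enrichment_score(
    ranking: RankedGeneList, genes, weight_exponent: float = 1.0
) -> ESResult:
    """Weighted Kolmogorov–Smirnov-like running-sum enrichment score.

    ``genes`` is the member list; genes absent from the ranking are
    dropped (universe restriction). Raises if no member remains or if all
    member statistics are zero (the walk would be undefined).
    """
    pos_map = ranking.positions()
    hits = sorted(pos_map[g] for g in set(genes) if g in pos_map)
    if not hits:
        raise ValueError("gene set has no members in the ranking")
    n = len(ranking)
    k = len(hits)
    if k == n:
        raise ValueError("gene set covers the entire ranking")
    w = np.abs(ranking.stats[hits]) ** weight_exponent
    total = w.sum()
    if total == 0:
        raise ValueError("zero total hit weight; enrichment score undefined")
    inc = np.full(n, -1.0 / (n - k))
    inc[hits] = w / total
    run = np.cumsum(inc)
    mx, mn = run.max(), run.min()
    es = float(mx if mx >= -mn else mn)  # ties resolved toward positive
    es = min(1.0, max(-1.0, es))  # |ES| <= 1 holds exactly; trim fp residue
    hits = np.asarray(hits)
    if es > 0:
        extremum = int(np.argmax(run))
        lead = hits[hits <= extremum]
    elif es < 0:
        extremum = int(np.argmin(run))
        lead = hits[hits >= extremum]
    else:
        lead = np.array([], dtype=int)
    return ESResult(
        es=es,
        running_sum=run,
        leading_edge=[str(g) for g in ranking.genes[lead]],
        hit_positions=hits,
    )


def _null_es_batch(
    stats: np.ndarray, k: int, n_perm: int, rng: np.random.Generator,
    weight_exponent: float = 1.0,
) -> np.ndarray:
    """ES of ``n_perm`` random size-k sets, vectorized.

    The walk's extrema can only occur at hit positions (maxima, just
    after the increment) or immediately before a hit (minima), so only
    the k sorted hit positions per permutation are needed.
    """
    n = len(stats)
    keys = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(keys, k, axis=1)[:, :k], axis=1)
    w = np.abs(stats[pos]) ** weight_exponent
    total = w.sum(axis=1, keepdims=True)
    ok = total[:, 0] > 0
    total[~ok] = 1.0
    cumw = np.cumsum(w, axis=1) / total
    d = 1.0 / (n - k)
    drop = (pos - np.arange(k)[None, :]) * d  # misses accumulated before each hit
    at_hit = cumw - drop
    before_hit = cumw - w / total - drop
    mx = at_hit.max(axis=1)  # walk maxima occur only at hit increments
    mn = np.minimum(before_hit.min(axis=1), 0.0)
    es = np.where(mx >= -mn, mx, mn)
    es[~ok] = 0.0
    return np.clip(es, -1.0, 1.0)


@dataclass
class PermutationResult:
    es: float
    nes: float
    pval: float
    null_es: np.ndarray
    n_same_sign: int
    leading_edge: list[str]
    flagged: bool = False


def permutation_null(
    ranking: RankedGeneList,
    genes,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> PermutationResult:
    """Gene-permutation null, sign-conditioned p-value, and NES."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs = enrichment_score(ranking, genes, weight_exponent=weight_exponent)
    rng = np.random.default_rng(seed)
    null = _null_es_batch(
        ranking.stats, len(obs.hit_positions), n_perm, rng, weight_exponent
    )
    if obs.es > 0:
        same = null[null > 0]
    elif obs.es < 0:
        same = null[null < 0]
    else:
        same = np.array([])
    m = len(same)
    if m == 0:
        return PermutationResult(
            es=obs.es, nes=float("nan"), pval=1.0, null_es=null,
            n_same_sign=0, leading_edge=obs.leading_edge, flagged=True,
        )
    b = int(np.sum(np.abs(same) >= abs(obs.es)))
    pval = (1 + b) / (1 + m)
    nes = obs.es / np.abs(same).mean()
    return PermutationResult(
        es=obs.es, nes=float(nes), pval=float(pval), null_es=null,
        n_same_sign=m, leading_edge=obs.leading_edge,
    )


def adjust_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return sps.false_discovery_control(p, method="bh")


def run_gsea(
    ranking: RankedGeneList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Score every gene set in the collection against the ranking.

    Sets outside [min_size, max_size] after restriction to the ranked
    universe are skipped (with a warning). Each set draws its null from
    an independent substream of ``seed`` keyed by its (sorted) name, so
    results do not depend on collection order.
    """
    pos_map = ranking.positions()
    seed_of = {name: i for i, name in enumerate(sorted(collection.names()))}
    rows = []
    for gs in collection:
        members_in = [g for g in dict.fromkeys(gs.genes) if g in pos_map]
        size = len(members_in)
        if size < min_size or size > max_size:
            warnings.warn(
                f"set {gs.name!r} size {size} outside [{min_size}, {max_size}]; skipped",
                stacklevel=2,
            )
            continue
        sub_seed = np.random.SeedSequence([seed, seed_of[gs.name]])
        try:
            res = permutation_null(
                ranking,
                members_in,
                n_perm=n_perm,
                seed=sub_seed,
                weight_exponent=weight_exponent,
            )
        except ValueError as exc:
            warnings.warn(f"set {gs.name!r} skipped: {exc}", stacklevel=2)
            continue
        rows.append(
            {
                "set_name": gs.name,
                "size": size,
                "es": res.es,
                "nes": res.nes,
                "pval": res.pval,
                "leading_edge": res.leading_edge,
                "flagged": res.flagged,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "size", "es", "nes", "pval", "padj",
                     "leading_edge", "flagged"]
        )
    df = pd.DataFrame(rows)
    df["padj"] = adjust_fdr(df["pval"].to_numpy())
    return df[["set_name", "size", "es", "nes", "pval", "padj",
               "leading_edge", "flagged"]]


def partition_by_nes(
    results: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Significant sets split by NES sign: (positive, negative) name lists."""
    sig = results[results["padj"] < alpha]
    pos = sig[sig["nes"] > 0]["set_name"].tolist()
    neg = sig[sig["nes"] < 0]["set_name"].tolist()
    return pos, neg


@dataclass
class LineageEnrichmentSummary:
    per_lineage: dict[str, tuple[list[str], list[str]]]
    intersection_positive: list[str]
    intersection_negative: list[str]


def intersect_lineages(per_lineage) -> LineageEnrichmentSummary:
    """Pathways significant in every lineage, per NES-sign group.

    ``per_lineage`` maps lineage label → (positive names, negative names).
    """
    per_lineage = dict(per_lineage)
    if len(per_lineage) < 2:
        raise ValueError("intersection needs at least two lineages")
    pos_sets = [set(p) for p, _ in per_lineage.values()]
    neg_sets = [set(n) for _, n in per_lineage.values()]
    inter_pos = sorted(set.intersection(*pos_sets))
    inter_neg = sorted(set.intersection(*neg_sets))
    return LineageEnrichmentSummary(
        per_lineage=per_lineage,
        intersection_positive=inter_pos,
        intersection_negative=inter_neg,
    )
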