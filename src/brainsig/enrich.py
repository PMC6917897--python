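"""Pre-ranked gene-set enrichment, leading-edge candidates and overlap.

Given a ranked list L (genes in descending mean-correlation order), the
enrichment score of a set S walks L accumulating |mean_r|^p / N_R on each
hit and subtracting 1/(N - N_H) on each miss; ES is the signed maximum
deviation of this running sum from zero. With p = 0 this reduces to the
classical Kolmogorov-Smirnov statistic between hit and miss ranks; p = 1
(the default, "weighted" scoring) emphasises genes with extreme scores.

The null is gene-tag permutation: ES of random same-size sets drawn without
replacement from the universe (a pre-ranked list has no phenotype labels to
permute). NES divides ES by the mean same-signed null ES; the FDR q of an
observed NES* is the sign-stratified ratio of the null tail fraction to the
observed tail fraction, capped at 1.

The leading edge of a positively enriched set is its members at or before
the running-sum peak (at or after the trough for negative ES); candidate
genes are ranked by the number of significant same-sign leading edges they
appear in, ties broken by |mean_r|, then gene id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import RankedList

DEFAULT_FDR_THRESHOLD = 0.05
DEFAULT_SET_SIZE_BOUNDS = (15, 500)


# ---------------------------------------------------------------------------
# enrichment score

@dataclass
class EnrichmentProfile:
    """Running-sum walk of one gene set along one ranked list."""

    running: np.ndarray          # value after each rank, length N
    es: float
    peak_rank: int               # 1-based position of the signed extreme
    N: int
    N_H: int
    N_R: float
    p: float
    hit_ranks: np.ndarray        # 1-based ranks of the members


def enrichment_score(ranked: RankedList, members: Iterable[str],
                     p: float = 1.0) -> EnrichmentProfile:
    """Weighted running-sum enrichment score of a set against a ranked list."""
    genes = ranked.genes
    scores = ranked.scores
    N = len(genes)
    member_set = set(members)
    hit = np.fromiter((g in member_set for g in genes), bool, count=N)
    N_H = int(hit.sum())
    if N_H < 1 or N_H >= N:
        raise ValueError("set must hit at least one and not all ranked genes")
    w = np.abs(scores) ** p
    N_R = float(w[hit].sum())
    if N_R == 0:
        raise ValueError("degenerate weights: every hit has zero score")
    step = np.where(hit, w / N_R, -1.0 / (N - N_H))
    running = np.cumsum(step)
    hi = float(max(running.max(), 0.0))
    lo = float(min(running.min(), 0.0))
    if hi >= -lo:
        es, peak = hi, int(np.argmax(running)) + 1
    else:
        es, peak = lo, int(np.argmin(running)) + 1
    return EnrichmentProfile(running=running, es=es, peak_rank=peak, N=N,
                             N_H=N_H, N_R=N_R, p=p,
                             hit_ranks=np.flatnonzero(hit) + 1)


def _es_batch(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """ES for many same-size sets given sorted 0-based hit positions (B, k).

    Uses the fact that between hits the running sum falls linearly, so its
    extremes occur immediately after a hit or immediately before one.
    """
    B, k = hits.shape
    N = len(weights)
    wh = weights[hits]
    cw = np.cumsum(wh, axis=1)
    NR = cw[:, -1:]
    NR = np.where(NR == 0, np.nan, NR)
    m = 1.0 / (N - k)
    miss_before = hits + 1 - np.arange(1, k + 1)
    after = cw / NR - miss_before * m
    before = (cw - wh) / NR - miss_before * m
    hi = np.maximum(after.max(axis=1), 0.0)
    lo = np.minimum(before.min(axis=1), 0.0)
    es = np.where(hi >= -lo, hi, lo)
    return np.nan_to_num(es, nan=0.0)


def permutation_null(ranked: RankedList, set_size: int, n_perm: int,
                     rng: np.random.Generator, p: float = 1.0) -> np.ndarray:
    """Null ES sample from random same-size sets (gene-tag permutation)."""
    N = len(ranked)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if set_size >= N:
        raise ValueError("set_size must be smaller than the universe")
    w = np.abs(ranked.scores) ** p
    u = rng.random((n_perm, N))
    idx = np.argpartition(u, set_size, axis=1)[:, :set_size]
    idx.sort(axis=1)
    return _es_batch(w, idx)


class NullCache:
    """Per-set-size cache of permutation null ES samples for one list."""

    def __init__(self, ranked: RankedList, n_perm: int, seed: int,
                 p: float = 1.0) -> None:
        self.ranked = ranked
        self.n_perm = n_perm
        self.p = p
        self._rng = np.random.default_rng(seed)
        self._store: dict[int, np.ndarray] = {}

    def __call__(self, set_size: int) -> np.ndarray:
        if set_size not in self._store:
            self._store[set_size] = permutation_null(
                self.ranked, set_size, self.n_perm, self._rng, self.p)
        return self._store[set_size]


# ---------------------------------------------------------------------------
# normalization, significance, FDR

def _same_sign_stats(es: float, nulls: np.ndarray,
                     n_perm: int) -> tuple[float, float, bool]:
    """(NES, nominal p, floored?) of one observed ES against its null."""
    if es == 0:
        return 0.0, 1.0, False
    same = nulls[nulls > 0] if es > 0 else nulls[nulls < 0]
    if len(same) == 0:
        return np.nan, 1.0 / (n_perm + 1), True
    denom = float(np.abs(same).mean())
    nes = es / denom
    extreme = (same >= es).sum() if es > 0 else (same <= es).sum()
    pval = extreme / len(same)
    if pval == 0.0:
        pval = 1.0 / (n_perm + 1)
    return nes, pval, False


def _null_nes(nulls: np.ndarray) -> np.ndarray:
    """Normalize a null ES sample by its own signed means."""
    pos = nulls[nulls > 0]
    neg = nulls[nulls < 0]
    out = np.zeros_like(nulls)
    if len(pos):
        out[nulls > 0] = nulls[nulls > 0] / pos.mean()
    if len(neg):
        out[nulls < 0] = nulls[nulls < 0] / np.abs(neg.mean())
    return out


def _fdr_q(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified NES-ratio FDR, capped at 1."""
    q = np.ones_like(obs_nes, dtype=float)
    finite = np.isfinite(obs_nes)
    pos_obs = obs_nes[finite & (obs_nes > 0)]
    neg_obs = obs_nes[finite & (obs_nes < 0)]
    null_pos = null_nes[null_nes > 0]
    null_neg = null_nes[null_nes < 0]
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes) or nes == 0:
            continue
        if nes > 0:
            frac_null = ((null_pos >= nes).sum() / len(null_pos)
                         if len(null_pos) else 0.0)
            frac_obs = (pos_obs >= nes).sum() / len(pos_obs)
        else:
            frac_null = ((null_neg <= nes).sum() / len(null_neg)
                         if len(null_neg) else 0.0)
            frac_obs = (neg_obs <= nes).sum() / len(neg_obs)
        q[i] = min(frac_null / frac_obs, 1.0) if frac_obs > 0 else 1.0
    return q


def leading_edge(profile: EnrichmentProfile,
                 ranked: RankedList) -> list[str]:
    """Members driving the enrichment (at/before peak, or at/after trough)."""
    genes = ranked.genes
    if profile.es > 0:
        ranks = profile.hit_ranks[profile.hit_ranks <= profile.peak_rank]
    elif profile.es < 0:
        ranks = profile.hit_ranks[profile.hit_ranks >= profile.peak_rank]
    else:
        return []
    return [genes[r - 1] for r in ranks]


@dataclass
class EnrichmentReport:
    """Scored gene sets for one ranked list."""

    results: pd.DataFrame        # set_id, size, es, nes, nominal_p, fdr_q, ...
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
    profiles: dict[str, EnrichmentProfile] = field(default_factory=dict)

    def significant(self, sign: int) -> pd.DataFrame:
        r = self.results
        mask = (r["fdr_q"] < self.fdr_threshold) & (np.sign(r["es"]) == sign)
        return r[mask]

    @property
    def s_plus(self) -> pd.DataFrame:
        return self.significant(+1)

    @property
    def s_minus(self) -> pd.DataFrame:
        return self.significant(-1)

    def member_gene_union(self, sign: int | None = None) -> set[str]:
        """All genes of significant sets (both signs unless given)."""
        frames = ([self.significant(sign)] if sign is not None
                  else [self.s_plus, self.s_minus])
        out: set[str] = set()
        for fr in frames:
            for members in fr["members"]:
                out.update(members)
        return out


def score_gene_sets(ranked: RankedList, gene_sets: Mapping[str, Sequence[str]],
                    p: float = 1.0, n_perm: int = 1000, seed: int = 0,
                    size_bounds: tuple[int, int] = DEFAULT_SET_SIZE_BOUNDS,
                    fdr_threshold: float = DEFAULT_FDR_THRESHOLD
                    ) -> EnrichmentReport:
    """Score every admissible gene set against one ranked list.

    Sets are intersected with the ranked universe and kept if their
    intersected size lies within ``size_bounds``. Null ES samples are cached
    per set size and shared across sets.
    """
    universe = set(ranked.genes)
    cache = NullCache(ranked, n_perm=n_perm, seed=seed, p=p)
    rows = []
    profiles: dict[str, EnrichmentProfile] = {}
    null_nes_chunks = []
    for set_id in sorted(gene_sets):
        members = sorted(universe.intersection(gene_sets[set_id]))
        if not size_bounds[0] <= len(members) <= size_bounds[1]:
            continue
        prof = enrichment_score(ranked, members, p=p)
        nulls = cache(len(members))
        nes, pval, floored = _same_sign_stats(prof.es, nulls, n_perm)
        profiles[set_id] = prof
        rows.append({"set_id": set_id, "size": len(members), "es": prof.es,
                     "nes": nes, "nominal_p": pval, "p_floored": floored,
                     "peak_rank": prof.peak_rank,
                     "members": members,
                     "leading_edge": leading_edge(prof, ranked)})
    if not rows:
        return EnrichmentReport(results=pd.DataFrame(
            columns=["set_id", "size", "es", "nes", "nominal_p", "p_floored",
                     "peak_rank", "members", "leading_edge", "fdr_q"]),
            fdr_threshold=fdr_threshold)
    for size in {r["size"] for r in rows}:
        null_nes_chunks.append(_null_nes(cache(size)))
    res = pd.DataFrame(rows)
    res["fdr_q"] = _fdr_q(res["nes"].to_numpy(float),
                          np.concatenate(null_nes_chunks))
    return EnrichmentReport(results=res, fdr_threshold=fdr_threshold,
                            profiles=profiles)


# ---------------------------------------------------------------------------
# candidate ranking

def candidate_ranking(report: EnrichmentReport, ranked: RankedList,
                      sign: int, top: int = 10) -> pd.DataFrame | None:
    """Top genes by leading-edge membership across significant sets.

    Returns None when no set of the requested sign survives the FDR
    threshold — an empty candidate list is a valid outcome, not an error.
    Ordering: membership count descending, then |mean_r| descending, then
    gene id.
    """
    sig = report.significant(sign)
    if sig.empty:
        return None
    counts = Counter(g for edge in sig["leading_edge"] for g in edge)
    mean_r = dict(zip(ranked.genes, ranked.scores))
    tab = pd.DataFrame({"gene_id": list(counts),
                        "n_leading_edge_sets": list(counts.values())})
    tab["mean_r"] = tab["gene_id"].map(mean_r)
    tab["_abs"] = tab["mean_r"].abs()
    tab = tab.sort_values(["n_leading_edge_sets", "_abs", "gene_id"],
                          ascending=[False, False, True], kind="mergesort")
    return tab.drop(columns="_abs").head(top).reset_index(drop=True)


# ---------------------------------------------------------------------------
# cortical/subcortical overlap and over-representation

def round_half_up_pct(shared: int, union: int, digits: int = 1) -> float:
    """Percentage 100*shared/union, rounded half-up to the given digits."""
    if union == 0:
        return 0.0
    pct = Decimal(100 * shared) / Decimal(union)
    return float(pct.quantize(Decimal(1).scaleb(-digits), ROUND_HALF_UP))


@dataclass
class OverlapSummary:
    shared_sets: list[str]
    sets_only_a: list[str]
    sets_only_b: list[str]
    shared_genes: list[str]
    genes_only_a: list[str]
    genes_only_b: list[str]

    @property
    def set_pct(self) -> float:
        union = len(self.shared_sets) + len(self.sets_only_a) + len(self.sets_only_b)
        return round_half_up_pct(len(self.shared_sets), union)

    @property
    def gene_pct(self) -> float:
        union = (len(self.shared_genes) + len(self.genes_only_a)
                 + len(self.genes_only_b))
        return round_half_up_pct(len(self.shared_genes), union)


def overlap_analysis(genes_a: Iterable[str], genes_b: Iterable[str],
                     sets_a: Iterable[str], sets_b: Iterable[str]
                     ) -> OverlapSummary:
    """Shared/specific gene sets and genes between two compartments."""
    ga, gb = set(genes_a), set(genes_b)
    sa, sb = set(sets_a), set(sets_b)
    return OverlapSummary(
        shared_sets=sorted(sa & sb),
        sets_only_a=sorted(sa - sb), sets_only_b=sorted(sb - sa),
        shared_genes=sorted(ga & gb),
        genes_only_a=sorted(ga - gb), genes_only_b=sorted(gb - ga))


def ora(gene_list: Iterable[str], gene_sets: Mapping[str, Sequence[str]],
        universe: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    Upper-tail probability of at least the observed overlap, with
    Benjamini-Hochberg adjustment across the tested sets.
    """
    uni = set(universe)
    lst = set(gene_list)
    if not lst <= uni:
        raise ValueError("gene list must be a subset of the universe")
    M, n = len(uni), len(lst)
    rows = []
    for set_id in sorted(gene_sets):
        members = uni.intersection(gene_sets[set_id])
        k = len(lst & members)
        if n == 0 or k == 0:
            pval = 1.0
        else:
            pval = float(stats.hypergeom.sf(k - 1, M, len(members), n))
        rows.append({"set_id": set_id, "set_size": len(members),
                     "overlap": k, "p": pval})
    res = pd.DataFrame(rows)
    if len(res):
        from statsmodels.stats.multitest import multipletests
        res["q"] = multipletests(res["p"], method="fdr_bh")[1]
    return res


def network_table(report: EnrichmentReport,
                  jaccard_threshold: float = 0.25
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node/edge tables of significant sets for generic network viewers.

    Nodes are significant sets; edges connect pairs whose member Jaccard
    overlap meets the threshold.
    """
    sig = pd.concat([report.s_plus, report.s_minus])
    nodes = sig[["set_id", "size", "es", "nes", "fdr_q"]].reset_index(drop=True)
    members = {r.set_id: set(r.members) for r in sig.itertuples()}
    edges = []
    ids = sorted(members)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = len(members[a] & members[b])
            union = len(members[a] | members[b])
            j = inter / union if union else 0.0
            if j >= jaccard_threshold:
                edges.append({"source": a, "target": b, "jaccard": j})
    return nodes, pd.DataFrame(edges, columns=["source", "target", "jaccard"])
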