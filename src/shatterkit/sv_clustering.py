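"""Proximity clustering of SV junctions and per-cluster statistics.

The chance model treats breakends as points thrown uniformly on the genome:
with ``N`` breakends over genome length ``G``, the probability that two
independent breakends land within distance ``d`` of each other is
approximated as ``p = 1 - exp(-2 N d / G)``.  Clusters are merged
agglomeratively while the closest same-chromosome pair of breakends between
two clusters is closer than chance at level ``alpha``.  This is a documented
re-derivation of the behaviour of proximity-based SV clustering tools, not a
claim of bit-compatibility with any of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .sv_io import BreakpointJunction, classify_orientation

#: exact multinomial enumeration is used up to this total count
EXACT_MULTINOMIAL_MAX_N = 40


@dataclass
class SVCluster:
    """A set of junctions grouped by proximity, with derived statistics."""

    cluster_id: int
    junctions: list[BreakpointJunction]
    footprints: dict[str, tuple[int, int]]
    orientation_counts: dict[str, int]
    n_interleaved: int
    n_interleaved_pairs: int
    fragment_join_p: float | None
    oscillation_run2: int | None = None
    oscillation_run3: int | None = None

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)


# ---------------------------------------------------------------------------
# chance model / clustering

def _breakends(j: BreakpointJunction) -> list[tuple[str, int]]:
    return [(j.chrom1, j.pos1), (j.chrom2, j.pos2)]


def proximity_pvalue(d: float, n_breakends: int, genome_length: float) -> float:
    """P(two independent breakends fall within distance ``d``)."""
    return 1.0 - math.exp(-2.0 * n_breakends * d / genome_length)


def cluster_junctions(junctions: Sequence[BreakpointJunction],
                      genome_lengths: dict[str, int],
                      alpha: float = 1e-3,
                      bonferroni: bool = False,
                      ) -> list[SVCluster]:
    """Group junctions into clusters unlikely to co-locate by chance.

    Agglomerative merging: repeatedly merge the pair of clusters whose
    minimum same-chromosome breakend distance gives a chance probability
    below ``alpha`` (optionally Bonferroni-corrected over the candidate
    merges at each step), until no such pair remains.  Translocation
    junctions carry breakends on two chromosomes and therefore connect
    clusters on both partners.  Ties break deterministically on the leftmost
    member coordinate, then junction id.
    """
    if not junctions:
        raise ValueError("at least one junction is required")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    norm = [j.normalized() for j in junctions]
    used_chroms = {c for j in norm for c in (j.chrom1, j.chrom2)}
    missing = used_chroms - set(genome_lengths)
    if missing:
        raise ValueError(f"genome_lengths missing chromosomes: {sorted(missing)}")
    G = float(sum(genome_lengths.values()))
    N = 2 * len(norm)

    members: list[list[int]] = [[i] for i in range(len(norm))]

    def min_dist(a: list[int], b: list[int]) -> float:
        best = math.inf
        for i in a:
            for ci, pi in _breakends(norm[i]):
                for j in b:
                    for cj, pj in _breakends(norm[j]):
                        if ci == cj:
                            best = min(best, abs(pi - pj))
        return best

    def sort_key(cluster: list[int]) -> tuple:
        j = norm[min(cluster, key=lambda i: (norm[i].chrom1, norm[i].pos1))]
        return (j.chrom1, j.pos1, j.id or "")

    while len(members) > 1:
        best = None  # (dist, key_a, key_b, ia, ib)
        n_candidates = 0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                d = min_dist(members[a], members[b])
                if math.isinf(d):
                    continue
                n_candidates += 1
                cand = (d, sort_key(members[a]), sort_key(members[b]), a, b)
                if best is None or cand < best:
                    best = cand
        if best is None:
            break
        threshold = alpha / n_candidates if bonferroni else alpha
        if proximity_pvalue(best[0], N, G) >= threshold:
            break
        _, _, _, a, b = best
        merged = sorted(members[a] + members[b])
        members = [m for i, m in enumerate(members) if i not in (a, b)]
        members.append(merged)

    members.sort(key=sort_key)
    return [build_cluster(cid, [norm[i] for i in idxs])
            for cid, idxs in enumerate(members)]


def build_cluster(cluster_id: int,
                  junctions: Sequence[BreakpointJunction]) -> SVCluster:
    """Assemble an SVCluster with footprints and orientation statistics."""
    norm = sorted((j.normalized() for j in junctions),
                  key=lambda j: (j.chrom1, j.pos1, j.chrom2, j.pos2))
    footprints: dict[str, tuple[int, int]] = {}
    for j in norm:
        for chrom, pos in _breakends(j):
            lo, hi = footprints.get(chrom, (pos, pos + 1))
            footprints[chrom] = (min(lo, pos), max(hi, pos + 1))
    counts = {c: 0 for c in ("D", "TD", "HH", "TT", "TRA")}
    for j in norm:
        counts[classify_orientation(j)] += 1
    intra = [counts["D"], counts["TD"], counts["HH"], counts["TT"]]
    p = fragment_join_pvalue(tuple(intra)) if sum(intra) > 0 else None
    n_inter, n_pairs = count_interleaved(norm, return_pairs=True)
    return SVCluster(
        cluster_id=cluster_id, junctions=list(norm), footprints=footprints,
        orientation_counts=counts, n_interleaved=n_inter,
        n_interleaved_pairs=n_pairs, fragment_join_p=p)


# ---------------------------------------------------------------------------
# interleaving

def _crossing(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Spans cross iff exactly one endpoint of b lies strictly inside a."""
    inside = (a[0] < b[0] < a[1]) + (a[0] < b[1] < a[1])
    return inside == 1


def count_interleaved(cluster_junctions: Sequence[BreakpointJunction],
                      return_pairs: bool = False):
    """Number of junctions that interleave (cross) with >=1 other member.

    Two intrachromosomal junctions on the same chromosome interleave iff
    exactly one breakend of one lies strictly inside the other's span —
    crossing, not nested and not disjoint.  The pairwise crossing count is
    exposed for diagnostics via ``return_pairs``.
    """
    spans = [(j.chrom1, j.span) for j in cluster_junctions
             if j.is_intrachromosomal]
    involved = [False] * len(spans)
    n_pairs = 0
    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            if spans[i][0] != spans[j][0]:
                continue
            if _crossing(spans[i][1], spans[j][1]) or _crossing(spans[j][1],
                                                                spans[i][1]):
                involved[i] = involved[j] = True
                n_pairs += 1
    n = sum(involved)
    return (n, n_pairs) if return_pairs else n


# ---------------------------------------------------------------------------
# fragment-join test

def _enumerate_compositions(n: int, parts: int):
    if parts == 1:
        yield (n,)
        return
    for head in range(n + 1):
        for tail in _enumerate_compositions(n - head, parts - 1):
            yield (head, *tail)


def _multinomial_logpmf(counts: np.ndarray, n: int) -> np.ndarray:
    return (gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
            - n * math.log(4.0))


def fragment_join_pvalue(orientation_counts: tuple[int, int, int, int]
                         ) -> float | None:
    """Goodness-of-fit p-value of the four orientation classes vs (1/4,)*4.

    A high p-value means the D/TD/HH/TT classes are as evenly represented as
    expected under random rejoining of fragments.  Exact multinomial (sum of
    probabilities of outcomes no more probable than the observed one) up to
    ``EXACT_MULTINOMIAL_MAX_N``; chi-square with 3 df beyond.
    """
    counts = tuple(int(c) for c in orientation_counts)
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise ValueError("need four non-negative orientation counts")
    n = sum(counts)
    if n == 0:
        return None
    if n <= EXACT_MULTINOMIAL_MAX_N:
        outcomes = np.array(list(_enumerate_compositions(n, 4)), dtype=float)
        logp = _multinomial_logpmf(outcomes, n)
        obs = _multinomial_logpmf(np.array([counts], dtype=float), n)[0]
        return min(1.0, float(np.exp(logp[logp <= obs + 1e-9]).sum()))
    res = stats.chisquare(counts, f_exp=[n / 4.0] * 4)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# CN oscillation runs

def max_oscillation_run(cn_states: Sequence[float], k: int,
                        mode: str = "segments") -> int:
    """Longest run of consecutive CN states that oscillate among <= k states.

    States are discretized by rounding to the nearest integer.  Within a
    qualifying run every adjacent pair differs and at most ``k`` distinct
    states appear.  ``mode='segments'`` (default) measures run length in
    segments; ``mode='transitions'`` in state changes (segments - 1).
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if mode not in ("segments", "transitions"):
        raise ValueError("mode must be 'segments' or 'transitions'")
    states = [int(round(float(s))) for s in cn_states]
    if not states:
        return 0
    best = 1
    for i in range(len(states)):
        distinct = {states[i]}
        j = i
        while (j + 1 < len(states) and states[j + 1] != states[j]
               and len(distinct | {states[j + 1]}) <= k):
            distinct.add(states[j + 1])
            j += 1
        best = max(best, j - i + 1)
    return best if mode == "segments" else best - 1


def cluster_oscillation_runs(cluster: SVCluster,
                             cn_segments,
                             min_seg_len: int = 10_000,
                             ) -> tuple[int, int]:
    """(run2, run3) over the ordered CN states inside the cluster footprint.

    Segments shorter than ``min_seg_len`` are dropped before computing runs;
    runs are taken per footprint chromosome and the maximum reported.
    """
    run2 = run3 = 0
    for chrom, (lo, hi) in sorted(cluster.footprints.items()):
        states = [s.total_cn for s in sorted(
            (s for s in cn_segments
             if s.chrom == chrom and s.start < hi and s.end > lo
             and s.length >= min_seg_len),
            key=lambda s: s.start)]
        if states:
            run2 = max(run2, max_oscillation_run(states, 2))
            run3 = max(run3, max_oscillation_run(states, 3))
    return run2, run3


def clusters_to_frame(clusters: Sequence[SVCluster]) -> pd.DataFrame:
    """One row per cluster with all statistics (the cluster report)."""
    rows = []
    for c in clusters:
        fp = ";".join(f"{ch}:{lo}-{hi}"
                      for ch, (lo, hi) in sorted(c.footprints.items()))
        rows.append({
            "cluster_id": c.cluster_id,
            "n_junctions": c.n_junctions,
            "footprints": fp,
            **{f"n_{k}": v for k, v in c.orientation_counts.items()},
            "n_interleaved": c.n_interleaved,
            "n_interleaved_pairs": c.n_interleaved_pairs,
            "fragment_join_p": (np.nan if c.fragment_join_p is None
                                else c.fragment_join_p),
            "oscillation_run2": (np.nan if c.oscillation_run2 is None
                                 else c.oscillation_run2),
            "oscillation_run3": (np.nan if c.oscillation_run3 is None
                                 else c.oscillation_run3),
        })
    return pd.DataFrame(rows)
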