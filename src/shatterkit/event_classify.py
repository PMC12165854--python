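"""Simple/complex and chromothripsis-like classification of SV clusters,
fold-back (BFB) junction detection and breakpoint repair signatures.

The chromothripsis-like call uses four criteria: cluster size >= 5 junctions,
fragment-join goodness-of-fit p >= 0.05, >= 4 interleaved junctions, and CN
oscillation runs >= 4 between 2 states or >= 5 between 3 states; the verdict
requires at least 3 of the 4.  When a criterion cannot be evaluated (no CN
data, no intrachromosomal junctions) it is treated as unknown and the
requirement scales to ``ceil(3/4 * n_evaluable)`` — conservative, since an
unknown never counts as met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sv_io import BreakpointJunction, CNSegment, classify_orientation
from .sv_clustering import SVCluster, cluster_oscillation_runs

COMPLEX_MIN_JUNCTIONS = 3


@dataclass(frozen=True)
class ClassifyThresholds:
    min_cluster_size: int = 5
    min_fragment_join_p: float = 0.05
    min_interleaved: int = 4
    min_run2: int = 4
    min_run3: int = 5
    min_criteria: int = 3
    min_seg_len: int = 10_000
    foldback_max_gap: int = 5_000
    nhej_fraction: float = 0.8


@dataclass
class ChromothripsisCall:
    """Per-cluster verdict with the individual criterion flags.

    Flags are ``True``/``False``/``None`` (unknown — not evaluable)."""

    cluster_id: int
    size_ok: bool | None
    fragment_join_ok: bool | None
    interleaved_ok: bool | None
    oscillation_ok: bool | None
    n_criteria_met: int
    n_criteria_evaluable: int
    verdict: str
    foldback_present: bool
    frac_small_insertions: float | None


def classify_complexity(cluster: SVCluster) -> str:
    """'complex' iff the cluster holds >= 3 interconnected junctions."""
    return "complex" if cluster.n_junctions >= COMPLEX_MIN_JUNCTIONS else "simple"


def detect_foldback(junction: BreakpointJunction,
                    max_gap: int = 5_000) -> bool:
    """Fold-back inversion: an inverted intrachromosomal junction whose
    breakends lie within ``max_gap`` of each other."""
    j = junction.normalized()
    if not j.is_intrachromosomal:
        return False
    if classify_orientation(j) not in ("HH", "TT"):
        return False
    return abs(j.pos2 - j.pos1) <= max_gap


def repair_signature(junctions: Sequence[BreakpointJunction],
                     small_range: tuple[int, int] = (0, 6),
                     nhej_fraction: float = 0.8) -> dict:
    """Summary of junction insertion lengths as a repair-mechanism readout.

    Reports the fraction of junctions whose insertion length lies in
    ``small_range`` (NHEJ-style), a length histogram, and whether that
    fraction clears ``nhej_fraction``.
    """
    lens = [j.insertion_len for j in junctions if j.insertion_len is not None]
    n_excluded = len(junctions) - len(lens)
    if not lens:
        return {"n": 0, "n_excluded": n_excluded, "fraction_small": None,
                "histogram": {}, "nhej_consistent": None}
    lo, hi = small_range
    frac = sum(lo <= v <= hi for v in lens) / len(lens)
    hist: dict[int, int] = {}
    for v in lens:
        hist[v] = hist.get(v, 0) + 1
    return {"n": len(lens), "n_excluded": n_excluded,
            "fraction_small": frac,
            "histogram": dict(sorted(hist.items())),
            "nhej_consistent": frac >= nhej_fraction}


def classify_chromothripsis(cluster: SVCluster,
                            cn_segments: Sequence[CNSegment] | None = None,
                            thresholds: ClassifyThresholds | None = None,
                            ) -> ChromothripsisCall:
    """Evaluate the four chromothripsis criteria and return the verdict."""
    t = thresholds or ClassifyThresholds()

    size_ok: bool | None = cluster.n_junctions >= t.min_cluster_size
    fragment_join_ok: bool | None
    if cluster.fragment_join_p is None:
        fragment_join_ok = None
    else:
        fragment_join_ok = cluster.fragment_join_p >= t.min_fragment_join_p
    interleaved_ok: bool | None = cluster.n_interleaved >= t.min_interleaved

    oscillation_ok: bool | None
    if cn_segments is None:
        oscillation_ok = None
    else:
        run2, run3 = cluster_oscillation_runs(cluster, cn_segments,
                                              min_seg_len=t.min_seg_len)
        cluster.oscillation_run2, cluster.oscillation_run3 = run2, run3
        oscillation_ok = run2 >= t.min_run2 or run3 >= t.min_run3

    flags = [size_ok, fragment_join_ok, interleaved_ok, oscillation_ok]
    met = sum(1 for f in flags if f is True)
    evaluable = sum(1 for f in flags if f is not None)
    required = math.ceil(t.min_criteria / 4 * evaluable) if evaluable else math.inf

    complexity = classify_complexity(cluster)
    if complexity == "complex" and evaluable and met >= required:
        verdict = "chromothripsis_like"
    else:
        verdict = complexity

    foldback = any(detect_foldback(j, t.foldback_max_gap)
                   for j in cluster.junctions)
    sig = repair_signature(cluster.junctions, nhej_fraction=t.nhej_fraction)
    return ChromothripsisCall(
        cluster_id=cluster.cluster_id,
        size_ok=size_ok, fragment_join_ok=fragment_join_ok,
        interleaved_ok=interleaved_ok, oscillation_ok=oscillation_ok,
        n_criteria_met=met, n_criteria_evaluable=evaluable,
        verdict=verdict, foldback_present=foldback,
        frac_small_insertions=sig["fraction_small"])


def calls_to_frame(calls: Sequence[ChromothripsisCall]) -> pd.DataFrame:
    enc = {True: 1, False: 0, None: np.nan}
    return pd.DataFrame([{
        "cluster_id": c.cluster_id,
        "size_ok": enc[c.size_ok],
        "fragment_join_ok": enc[c.fragment_join_ok],
        "interleaved_ok": enc[c.interleaved_ok],
        "oscillation_ok": enc[c.oscillation_ok],
        "n_criteria_met": c.n_criteria_met,
        "n_criteria_evaluable": c.n_criteria_evaluable,
        "verdict": c.verdict,
        "foldback_present": int(c.foldback_present),
        "frac_small_insertions": (np.nan if c.frac_small_insertions is None
                                  else c.frac_small_insertions),
    } for c in calls])


def summarize_sample(calls: Sequence[ChromothripsisCall],
                     clusters: Sequence[SVCluster]) -> dict:
    """Per-sample roll-up: any chromothripsis-like event, chromosomes hit."""
    like = [c for c in calls if c.verdict == "chromothripsis_like"]
    by_id = {c.cluster_id: c for c in clusters}
    chroms = sorted({ch for call in like
                     for ch in by_id[call.cluster_id].footprints})
    return {"any_chromothripsis": bool(like),
            "n_chromothripsis_clusters": len(like),
            "chromosomes": chroms}
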