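"""Cohort-level copy-number analysis.

Lesion typing of segments, calling of the recurrent chr21q amplification,
derivation of the minimally amplified region (MAR) shared by all carriers, a
simplified permutation-based recurrence scan, lesion co-occurrence statistics
and the CNA-burden comparison.

The recurrence scan is a deliberately simplified, clearly labelled stand-in
for semi-parametric recurrence tools: per-bin amplification G-scores with a
per-sample circular-shift null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import _intervals as iv
from .sv_io import CNSegment

CNA_CLASSES = ("gain", "loss", "cnn_loh", "neutral")


def classify_cna(segment: CNSegment, baseline_ploidy: float = 2.0,
                 margin: float = 0.5) -> str:
    """Type one segment as gain / loss / cnn_loh / neutral.

    Gain and loss use a symmetric ``margin`` around the baseline ploidy;
    CNN-LOH requires a within-margin total CN *and* a positive LOH flag
    (an unknown flag can never produce a CNN-LOH call).
    """
    cn = segment.total_cn
    if cn >= baseline_ploidy + margin:
        return "gain"
    if cn <= baseline_ploidy - margin:
        return "loss"
    if segment.loh is True:
        return "cnn_loh"
    return "neutral"


def call_chr21amp(sample_segments: Sequence[CNSegment],
                  target_region: tuple[str, int, int],
                  cn_threshold: float = 2.5,
                  ) -> tuple[bool, list[tuple[str, int, int]]]:
    """Flag a sample as amplification carrier over ``target_region``.

    True iff at least one gain segment (CN >= ``cn_threshold``) overlaps the
    target; the amplified intervals are the merged union of all such
    segments (gaps of sub-threshold CN are excluded).
    """
    chrom, t_start, t_end = target_region
    if not any(s.chrom == chrom for s in sample_segments):
        warnings.warn(f"no segments on {chrom}; calling non-carrier")
        return False, []
    gains = [(s.start, s.end) for s in sample_segments
             if s.chrom == chrom and s.total_cn >= cn_threshold]
    hit = any(s < t_end and e > t_start for s, e in gains)
    if not hit:
        return False, []
    return True, [(chrom, s, e) for s, e in iv.merge(gains)]


@dataclass
class MARResult:
    """Minimal amplified region shared across supporting samples."""

    intervals: list[tuple[str, int, int]]
    n_supporting_samples: int
    genes: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)


class EmptyIntersectionError(ValueError):
    """All-sample intersection is empty; retry with ``min_support``."""


def compute_mar(amplified_by_sample: Mapping[str, Sequence[tuple[str, int, int]]],
                gene_annotation: pd.DataFrame | None = None,
                min_support: int | None = None,
                gene_mode: str = "contained") -> MARResult:
    """Intersect the amplified-interval unions of all positive samples.

    With ``min_support=k`` the strict all-sample intersection is relaxed to
    the region amplified in at least ``k`` samples.  Gene membership is by
    full containment by default (``gene_mode='overlap'`` relaxes this).
    """
    samples = {sid: ivs for sid, ivs in amplified_by_sample.items() if ivs}
    if not samples:
        raise ValueError("need at least one sample with amplified intervals")
    chroms = sorted({c for ivs in samples.values() for c, _, _ in ivs})

    result: list[tuple[str, int, int]] = []
    for chrom in chroms:
        per_sample = [
            iv.merge([(s, e) for c, s, e in ivs if c == chrom])
            for ivs in samples.values()]
        if min_support is None:
            acc = per_sample[0]
            for u in per_sample[1:]:
                acc = iv.intersect(acc, u)
        else:
            acc = iv.covered_at_least(per_sample, min_support)
        result.extend((chrom, s, e) for s, e in acc)

    if not result:
        raise EmptyIntersectionError(
            "no region is amplified in all supporting samples; consider "
            "relaxing with min_support=k (intersection over size-k subsets)")

    genes: list[str] = []
    if gene_annotation is not None:
        per_chrom = {chrom: [(s, e) for c, s, e in result if c == chrom]
                     for chrom in {c for c, _, _ in result}}
        for row in gene_annotation.itertuples(index=False):
            ivs = per_chrom.get(row.chrom, [])
            if gene_mode == "contained":
                ok = iv.contains(ivs, row.start, row.end)
            else:
                ok = any(row.start < e and row.end > s for s, e in ivs)
            if ok:
                genes.append(row.gene)

    return MARResult(intervals=result,
                     n_supporting_samples=len(samples),
                     genes=genes)


# ---------------------------------------------------------------------------
# recurrence scan

def recurrence_scan(cohort_segments: Sequence[CNSegment],
                    genome_lengths: Mapping[str, int],
                    bin_size: int = 1_000_000,
                    n_perm: int = 1000,
                    seed: int = 0) -> pd.DataFrame:
    """Per-bin amplification scores with circular-shift permutation q-values.

    The amplification G-score of a bin is the sum over samples of
    ``max(0, log2(CN/2))``, length-weighted across the bin.  The null rolls
    each sample's rasterized genome track by an independent uniform offset
    per permutation, preserving the per-sample segment-length distribution.
    Empirical p-values use the (1 + exceedances) / (1 + n_perm) estimator and
    are Benjamini-Hochberg adjusted.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable q-values")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome_lengths)
    bin_index: list[tuple[str, int, int]] = []
    offsets: dict[str, int] = {}
    for chrom in chroms:
        offsets[chrom] = len(bin_index)
        nb = -(-genome_lengths[chrom] // bin_size)  # ceil
        for b in range(nb):
            start = b * bin_size
            bin_index.append((chrom, start,
                              min(start + bin_size, genome_lengths[chrom])))
    n_bins = len(bin_index)

    samples = sorted({s.sample_id or "" for s in cohort_segments})
    sidx = {sid: i for i, sid in enumerate(samples)}
    S = np.zeros((len(samples), n_bins))
    for seg in cohort_segments:
        score = max(0.0, np.log2(max(seg.total_cn, 1e-9) / 2.0))
        if score == 0.0 or seg.chrom not in offsets:
            continue
        first = seg.start // bin_size
        last = (seg.end - 1) // bin_size
        for b in range(first, last + 1):
            lo = max(seg.start, b * bin_size)
            hi = min(seg.end, (b + 1) * bin_size)
            S[sidx[seg.sample_id or ""], offsets[seg.chrom] + b] += (
                score * (hi - lo) / bin_size)

    observed = S.sum(axis=0)
    exceed = np.zeros(n_bins)
    cols = np.arange(n_bins)
    for _ in range(n_perm):
        off = rng.integers(0, n_bins, size=len(samples))
        rolled = S[np.arange(len(samples))[:, None], (cols[None, :] - off[:, None]) % n_bins]
        exceed += rolled.sum(axis=0) >= observed - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    if observed.max() <= 0:
        pvals = np.ones(n_bins)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame({
        "chrom": [b[0] for b in bin_index],
        "start": [b[1] for b in bin_index],
        "end": [b[2] for b in bin_index],
        "score": observed,
        "p": pvals,
        "q": qvals,
    })


# ---------------------------------------------------------------------------
# lesion co-occurrence

def lesion_association(lesion_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Fisher exact tests, odds ratios and phi correlations.

    ``lesion_matrix`` is samples x lesions with values in {0, 1, NA}; rows
    with NA are dropped pairwise.  P-values are Benjamini-Hochberg adjusted
    across pairs.  Zero-margin tables give p = 1 and a missing odds ratio.
    """
    lesions = list(lesion_matrix.columns)
    if len(lesions) < 2:
        raise ValueError("need at least two lesions")
    rows = []
    for i in range(len(lesions)):
        for j in range(i + 1, len(lesions)):
            a, b = lesions[i], lesions[j]
            sub = lesion_matrix[[a, b]].dropna().astype(int)
            t11 = int(((sub[a] == 1) & (sub[b] == 1)).sum())
            t10 = int(((sub[a] == 1) & (sub[b] == 0)).sum())
            t01 = int(((sub[a] == 0) & (sub[b] == 1)).sum())
            t00 = int(((sub[a] == 0) & (sub[b] == 0)).sum())
            table = np.array([[t11, t10], [t01, t00]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                p, odds = 1.0, np.nan
            else:
                odds, p = stats.fisher_exact(table, alternative="two-sided")
            with np.errstate(invalid="ignore"):
                phi = (np.corrcoef(sub[a], sub[b])[0, 1]
                       if sub[a].nunique() > 1 and sub[b].nunique() > 1
                       else np.nan)
            rows.append({"lesion_a": a, "lesion_b": b,
                         "n11": t11, "n10": t10, "n01": t01, "n00": t00,
                         "fisher_p": p, "odds_ratio": odds, "phi": phi})
    out = pd.DataFrame(rows)
    out["fisher_p_adj"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# CNA burden

def count_cna_burden(sample_segments: Sequence[CNSegment],
                     exclude_chrom: str | None = "chr21",
                     baseline_ploidy: float = 2.0,
                     merge_gap: int = 1) -> int:
    """Number of CNAs: non-neutral segments after merging adjacent
    same-class segments (gap <= ``merge_gap``), excluding ``exclude_chrom``."""
    segs = sorted((s for s in sample_segments if s.chrom != exclude_chrom),
                  key=lambda s: (s.chrom, s.start))
    count = 0
    prev_chrom = prev_class = None
    prev_end = -1
    for s in segs:
        cls = classify_cna(s, baseline_ploidy)
        if cls == "neutral":
            prev_class = None
            continue
        adjacent = (s.chrom == prev_chrom and cls == prev_class
                    and s.start - prev_end <= merge_gap)
        if not adjacent:
            count += 1
        prev_chrom, prev_class, prev_end = s.chrom, cls, s.end
    return count


def cna_burden_test(burden_carriers: Sequence[float],
                    burden_noncarriers: Sequence[float],
                    exact_max_n: int = 25) -> dict:
    """Medians plus a two-sided rank-sum p comparing the two burden groups.

    Exact Mann-Whitney when both groups are small and tie-free; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(burden_carriers, dtype=float)
    y = np.asarray(burden_noncarriers, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both burden groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = ("exact" if x.size <= exact_max_n and y.size <= exact_max_n
              and not has_ties else "asymptotic")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"median_carriers": float(np.median(x)),
            "median_noncarriers": float(np.median(y)),
            "p": float(res.pvalue),
            "method": method}
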