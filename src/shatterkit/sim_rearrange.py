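"""Synthetic rearrangement generator.

Builds derivative chromosomes for three mechanisms — chromothripsis
(shatter, lose, shuffle, invert, rejoin), breakage-fusion-bridge cycles
(iterated break / fold-back / duplicate) and simple tandem duplication — and
derives from them the implied copy-number profile and junction calls, all
with ground-truth labels.  On top of the single-event machinery sit cohort-,
single-cell- and expression-level simulations that emulate the statistical
structure of a leukemia cohort carrying a recurrent single-allele
amplification of chr21q22.

All coordinates are 0-based half-open.  Every simulation takes a mandatory
integer seed (or an already-seeded ``numpy.random.Generator``); identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .sv_io import BreakpointJunction, CNSegment

FWD = "+"
REV = "-"

#: synthetic genome used by default; chr21 has its true GRCh38 length so the
#: amplification target sits at realistic coordinates
DEFAULT_GENOME: dict[str, int] = {
    "chr1": 100_000_000,
    "chr5": 80_000_000,
    "chr7": 60_000_000,
    "chr9": 45_000_000,
    "chr17": 35_000_000,
    "chr21": 46_709_983,
}

#: designated amplified core on chr21q22 (2.7 Mb) — the ground-truth MAR
CHR21_CORE: tuple[str, int, int] = ("chr21", 38_500_000, 41_200_000)

#: 24-gene panel standing in for the genes of the amplified core
MAR_GENES: list[str] = [
    "DYRK1A", "DSCR3", "MORC3", "PIGP", "TTC3",
    "ERG", "ETS2", "PSMG1", "BRWD1", "HMGN1",
    "WRB", "LCA5L", "SH3BGR", "B3GALT5", "IGSF5",
    "PCP4", "DSCAM", "BACE2", "PLAC4", "FAM3B",
    "MX2", "MX1", "TMPRSS2", "RIPK4",
]

#: subset of the panel whose expression responds to copy-number dosage
RESPONSIVE_GENES: list[str] = MAR_GENES[:5]


class DegenerateDrawError(ValueError):
    """Raised when a random draw yields an unusable (empty) derivative."""


def _distinct_uniform(rng: np.random.Generator, lo: int, hi: int,
                      n: int) -> np.ndarray:
    """n distinct uniform draws from [lo, hi) without materializing the range."""
    if hi - lo < n:
        raise ValueError("range too small for distinct draws")
    picked: set[int] = set()
    while len(picked) < n:
        for v in rng.integers(lo, hi, size=n - len(picked)).tolist():
            picked.add(int(v))
    return np.sort(np.fromiter(picked, dtype=np.int64))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is mandatory for reproducibility")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class Fragment:
    """A piece of source sequence used (possibly repeatedly) in a derivative."""

    chrom: str
    start: int
    end: int
    orientation: str = FWD
    copy_index: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")
        if self.orientation not in (FWD, REV):
            raise ValueError("orientation must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def inverted(self) -> "Fragment":
        flip = REV if self.orientation == FWD else FWD
        return Fragment(self.chrom, self.start, self.end, flip, self.copy_index)


@dataclass(frozen=True)
class DerivativeArrangement:
    """Ordered fragments of one derivative chromosome on one haplotype."""

    fragments: tuple[Fragment, ...]
    mechanism_label: str
    genome: tuple[tuple[str, int], ...]
    region: tuple[str, int, int]
    affected_allele: str = "A"

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("arrangement must contain at least one fragment")

    @property
    def genome_dict(self) -> dict[str, int]:
        return dict(self.genome)

    def chroms(self) -> list[str]:
        return sorted({f.chrom for f in self.fragments})


@dataclass
class SimTruth:
    """Ground-truth labels carried alongside simulated artifacts."""

    mechanism_label: str
    footprint: list[tuple[str, int, int]] = field(default_factory=list)
    junction_labels: list[str] = field(default_factory=list)
    sample_flags: dict[str, bool] = field(default_factory=dict)
    cell_clones: dict[str, str] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


def _freeze_genome(genome: dict[str, int]) -> tuple[tuple[str, int], ...]:
    return tuple(sorted(genome.items()))


def _reindex_copies(fragments: Sequence[Fragment]) -> tuple[Fragment, ...]:
    """Assign copy_index by order of appearance of each source piece."""
    seen: dict[tuple[str, int, int], int] = {}
    out = []
    for f in fragments:
        key = (f.chrom, f.start, f.end)
        idx = seen.get(key, 0)
        seen[key] = idx + 1
        out.append(Fragment(f.chrom, f.start, f.end, f.orientation, idx))
    return tuple(out)


def identity_arrangement(region: tuple[str, int, int],
                         genome: dict[str, int] | None = None
                         ) -> DerivativeArrangement:
    """The unrearranged chromosome containing ``region`` (a trivial baseline)."""
    genome = dict(DEFAULT_GENOME if genome is None else genome)
    chrom = region[0]
    return DerivativeArrangement(
        fragments=(Fragment(chrom, 0, genome[chrom], FWD),),
        mechanism_label="background",
        genome=_freeze_genome(genome), region=region)


# ---------------------------------------------------------------------------
# chromothripsis

def simulate_chromothripsis(region: tuple[str, int, int],
                            n_breakpoints: int,
                            retention_prob: float,
                            seed,
                            genome: dict[str, int] | None = None,
                            amplify_region: tuple[str, int, int] | None = None,
                            max_copies: int = 1,
                            min_amp_copies: int = 2,
                            permutation: Sequence[int] | None = None,
                            inversions: Sequence[bool] | None = None,
                            interchrom_region: tuple[str, int, int] | None = None,
                            interchrom_pieces: int = 2,
                            ) -> tuple[DerivativeArrangement, SimTruth]:
    """Shatter ``region`` at uniform positions and rejoin haphazardly.

    The region is cut at ``n_breakpoints`` distinct uniform positions into
    ``n_breakpoints + 1`` pieces; each piece is independently retained with
    ``retention_prob``, the retained pieces are shuffled uniformly, each is
    inverted with probability 1/2, and the result is reattached to the flanks
    of the region.

    When ``amplify_region`` is given, pieces overlapping it are always
    retained and used ``min_amp_copies..max_copies`` times, so that the whole
    of ``amplify_region`` gains copies on the affected allele (the mode used
    to plant amplification events in cohort simulations).  Other retained
    pieces then get 1..``max_copies`` uses.

    ``permutation``/``inversions`` override the random shuffle and flips —
    intended for tests that need e.g. the identity rearrangement.

    ``interchrom_region`` optionally shatters a second region on another
    chromosome into ``interchrom_pieces`` pieces that join the shuffle,
    yielding translocation junctions (off by default).
    """
    rng = _rng(seed)
    genome = dict(DEFAULT_GENOME if genome is None else genome)
    chrom, start, end = region
    if n_breakpoints < 2:
        raise ValueError("n_breakpoints must be >= 2")
    if end - start <= n_breakpoints:
        raise ValueError("region too short for requested breakpoints")
    if not 0.0 <= retention_prob <= 1.0:
        raise ValueError("retention_prob must lie in [0, 1]")
    chrom_len = genome[chrom]

    breaks = _distinct_uniform(rng, start + 1, end, n_breakpoints)
    bounds = [start, *breaks.tolist(), end]
    pieces = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    retained = rng.random(len(pieces)) < retention_prob
    copies = np.ones(len(pieces), dtype=int)
    if amplify_region is not None:
        if max_copies < min_amp_copies:
            raise ValueError("max_copies must be >= min_amp_copies")
        amp_c, amp_s, amp_e = amplify_region
        copies = rng.integers(1, max_copies + 1, size=len(pieces))
        for i, (s, e) in enumerate(pieces):
            if amp_c == chrom and s < amp_e and e > amp_s:
                retained[i] = True
                copies[i] = int(rng.integers(min_amp_copies, max_copies + 1))

    pool: list[Fragment] = []
    for i, (s, e) in enumerate(pieces):
        if retained[i]:
            for c in range(int(copies[i])):
                pool.append(Fragment(chrom, s, e, FWD, c))

    if interchrom_region is not None:
        f_chrom, f_start, f_end = interchrom_region
        if f_chrom == chrom:
            raise ValueError("interchrom_region must be on another chromosome")
        cuts = _distinct_uniform(rng, f_start + 1, f_end,
                                 interchrom_pieces - 1)
        f_bounds = [f_start, *cuts.tolist(), f_end]
        pool.extend(Fragment(f_chrom, f_bounds[i], f_bounds[i + 1], FWD)
                    for i in range(len(f_bounds) - 1))

    has_left = start > 0
    has_right = end < chrom_len
    if not pool and not has_left and not has_right:
        raise DegenerateDrawError("all fragments lost and no flanks remain")

    perm = (rng.permutation(len(pool)) if permutation is None
            else np.asarray(permutation))
    inv = (rng.random(len(pool)) < 0.5 if inversions is None
           else np.asarray(inversions, dtype=bool))
    shuffled = [pool[int(k)].inverted() if inv[int(k)] else pool[int(k)]
                for k in perm]

    frags: list[Fragment] = []
    if has_left:
        frags.append(Fragment(chrom, 0, start, FWD))
    frags.extend(shuffled)
    if has_right:
        frags.append(Fragment(chrom, end, chrom_len, FWD))

    arrangement = DerivativeArrangement(
        fragments=_reindex_copies(frags), mechanism_label="chromothripsis",
        genome=_freeze_genome(genome), region=region)
    truth = SimTruth(mechanism_label="chromothripsis", footprint=[region],
                     extra={"n_retained": int(retained.sum()),
                            "n_pieces": len(pieces)})
    return arrangement, truth


# ---------------------------------------------------------------------------
# breakage-fusion-bridge

def _cut_prefix(fragments: Sequence[Fragment], offset: int) -> list[Fragment]:
    """Prefix of an arrangement covering its first ``offset`` bases."""
    out: list[Fragment] = []
    remaining = offset
    for f in fragments:
        if remaining <= 0:
            break
        if f.length <= remaining:
            out.append(f)
            remaining -= f.length
        else:
            if f.orientation == FWD:
                out.append(Fragment(f.chrom, f.start, f.start + remaining,
                                    FWD, f.copy_index))
            else:
                out.append(Fragment(f.chrom, f.end - remaining, f.end,
                                    REV, f.copy_index))
            remaining = 0
    return out


def simulate_bfb(region: tuple[str, int, int],
                 n_cycles: int,
                 seed,
                 genome: dict[str, int] | None = None,
                 ) -> tuple[DerivativeArrangement, SimTruth]:
    """Iterate break-invert-duplicate cycles over ``region``.

    Each cycle picks a uniform break position along the current derivative,
    keeps the proximal part and mirrors it onto itself, creating an inverted
    fold-back junction and doubling copy counts of the retained material.
    The distal part of the arm (and anything beyond) is lost.
    """
    rng = _rng(seed)
    genome = dict(DEFAULT_GENOME if genome is None else genome)
    chrom, start, end = region
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if end - start < 2:
        raise ValueError("region must span at least 2 bp")
    chrom_len = genome[chrom]

    body: list[Fragment] = [Fragment(chrom, start, end, FWD)]
    for _ in range(n_cycles):
        total = sum(f.length for f in body)
        b = int(rng.integers(1, total))
        prefix = _cut_prefix(body, b)
        body = prefix + [f.inverted() for f in reversed(prefix)]

    frags: list[Fragment] = []
    if start > 0:
        frags.append(Fragment(chrom, 0, start, FWD))
    frags.extend(body)

    arrangement = DerivativeArrangement(
        fragments=_reindex_copies(frags), mechanism_label="bfb",
        genome=_freeze_genome({**genome, chrom: chrom_len}), region=region)
    truth = SimTruth(mechanism_label="bfb", footprint=[region],
                     extra={"n_cycles": n_cycles})
    return arrangement, truth


# ---------------------------------------------------------------------------
# simple SV

def simulate_simple_duplication(region: tuple[str, int, int],
                                n_copies: int,
                                genome: dict[str, int] | None = None,
                                ) -> tuple[DerivativeArrangement, SimTruth]:
    """Tandem-duplicate ``region`` so it appears ``n_copies`` times in total."""
    genome = dict(DEFAULT_GENOME if genome is None else genome)
    chrom, start, end = region
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2 for a duplication")
    chrom_len = genome[chrom]
    frags: list[Fragment] = []
    if start > 0:
        frags.append(Fragment(chrom, 0, start, FWD))
    for c in range(n_copies):
        frags.append(Fragment(chrom, start, end, FWD, c))
    if end < chrom_len:
        frags.append(Fragment(chrom, end, chrom_len, FWD))
    arrangement = DerivativeArrangement(
        fragments=tuple(frags), mechanism_label="simple_sv",
        genome=_freeze_genome(genome), region=region)
    truth = SimTruth(mechanism_label="simple_sv", footprint=[region],
                     extra={"n_copies": n_copies})
    return arrangement, truth


# ---------------------------------------------------------------------------
# derived artifacts

def derive_cn_profile(arrangement: DerivativeArrangement,
                      ploidy: int = 2) -> list[CNSegment]:
    """Total CN segments implied by an arrangement on one allele.

    Total CN at a base is ``(ploidy - 1)`` (the untouched alleles) plus the
    number of fragment copies covering it on the affected allele.  Segments
    are maximal constant-CN intervals tiling every chromosome the arrangement
    touches.  Fragments from chromosomes other than the rearranged one (the
    optional interchromosomal mode) count as copied-in material: their source
    chromosome keeps its ``ploidy`` baseline and gains the extra coverage.
    """
    genome = arrangement.genome_dict
    affected_chrom = arrangement.region[0]
    segments: list[CNSegment] = []
    for chrom in arrangement.chroms():
        length = genome[chrom]
        baseline = (ploidy - 1) if chrom == affected_chrom else ploidy
        bounds = {0, length}
        for f in arrangement.fragments:
            if f.chrom == chrom:
                bounds.update((f.start, f.end))
        edges = sorted(bounds)
        starts = [f.start for f in arrangement.fragments if f.chrom == chrom]
        ends = [f.end for f in arrangement.fragments if f.chrom == chrom]
        prev_cn = None
        seg_start = 0
        for lo, hi in zip(edges, edges[1:]):
            cover = sum(1 for s, e in zip(starts, ends) if s <= lo and hi <= e)
            cn = baseline + cover
            if prev_cn is None:
                prev_cn, seg_start = cn, lo
            elif cn != prev_cn:
                segments.append(CNSegment(chrom, seg_start, lo, float(prev_cn)))
                prev_cn, seg_start = cn, lo
        segments.append(CNSegment(chrom, seg_start, length, float(prev_cn)))
    return segments


def _contiguous(a: Fragment, b: Fragment) -> bool:
    if a.chrom != b.chrom or a.orientation != b.orientation:
        return False
    if a.orientation == FWD:
        return b.start == a.end
    return b.end == a.start


def derive_junctions(arrangement: DerivativeArrangement,
                     insertion_len_range: tuple[int, int] = (0, 6),
                     seed=0,
                     sample_id: str | None = None,
                     deduplicate: bool = True,
                     ) -> list[BreakpointJunction]:
    """Junction calls implied by non-contiguous adjacent fragment pairs.

    Breakend orientation follows the flanking fragment orientations: a
    forward fragment contributes its right (source) end with strand ``+``; a
    reverse fragment contributes its left end with strand ``-`` (and the
    mirror image for the downstream side of the join).  Each junction gets an
    untemplated insertion length drawn uniformly from ``insertion_len_range``
    (the NHEJ-style 0-6 bp signature); no templated insertions are produced.

    Identical junction coordinates arising from repeated fragment use (e.g. a
    tandem duplication used three times) collapse to one call by default,
    matching what an SV caller would report.
    """
    rng = _rng(seed)
    lo, hi = insertion_len_range
    if lo < 0 or hi < lo:
        raise ValueError("invalid insertion_len_range")
    junctions: list[BreakpointJunction] = []
    seen: set[tuple] = set()
    k = 0
    for a, b in zip(arrangement.fragments, arrangement.fragments[1:]):
        if _contiguous(a, b):
            continue
        if a.orientation == FWD:
            c1, p1, s1 = a.chrom, a.end, "+"
        else:
            c1, p1, s1 = a.chrom, a.start, "-"
        if b.orientation == FWD:
            c2, p2, s2 = b.chrom, b.start, "-"
        else:
            c2, p2, s2 = b.chrom, b.end, "+"
        j = BreakpointJunction(
            chrom1=c1, pos1=p1, strand1=s1,
            chrom2=c2, pos2=p2, strand2=s2,
            insertion_len=int(rng.integers(lo, hi + 1)),
            sample_id=sample_id, id=f"J{k}",
        ).normalized()
        key = (j.chrom1, j.pos1, j.strand1, j.chrom2, j.pos2, j.strand2)
        if deduplicate and key in seen:
            continue
        seen.add(key)
        junctions.append(j)
        k += 1
    return junctions


# ---------------------------------------------------------------------------
# simulation parameters

@dataclass
class SimParams:
    """Flat parameter bag for cohort / single-cell / expression simulations."""

    seed: int
    # single-event model
    n_breakpoints: int = 20
    retention_prob: float = 0.5
    bfb_cycles: int = 3
    insertion_len_range: tuple[int, int] = (0, 6)
    # cohort structure (defaults emulate 16/64 carriers and burden medians
    # around 6.5 vs 1)
    cohort_size: int = 64
    chr21amp_prevalence: float = 0.25
    p_chromothripsis_carrier: float = 0.3125
    burden_mean_carriers: float = 6.5
    burden_mean_noncarriers: float = 1.2
    p_tp53_carrier: float = 0.7
    p_tp53_noncarrier: float = 0.2
    p_jak2: float = 0.9
    # single-cell hierarchy (defaults reproduce the 107/179/162/1455 split)
    n_cells: int = 1903
    clone_fractions: tuple[float, float, float, float] = (
        107 / 1903, 179 / 1903, 162 / 1903, 1455 / 1903)
    ado_rate: float = 0.05
    # expression model
    amp_cn: int = 3
    dosage_factor: float = 1.0
    nb_dispersion: float = 0.5
    snps_per_gene: int = 3
    ase_depth: int = 30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        probs = [self.retention_prob, self.chr21amp_prevalence,
                 self.p_chromothripsis_carrier, self.p_tp53_carrier,
                 self.p_tp53_noncarrier, self.p_jak2, self.ado_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(f < 0 for f in self.clone_fractions):
            raise ValueError("clone fractions must be non-negative")
        if not math.isclose(sum(self.clone_fractions), 1.0, abs_tol=1e-9):
            raise ValueError("clone_fractions must sum to 1")
        if self.burden_mean_carriers < 0 or self.burden_mean_noncarriers < 0:
            raise ValueError("burden means must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.amp_cn < 2:
            raise ValueError("amp_cn must be >= 2")
        self.insertion_len_range = tuple(self.insertion_len_range)  # type: ignore


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class CohortBundle:
    """Per-sample segments, junctions, lesion table and ground truth."""

    segments: list[CNSegment]
    junctions: list[BreakpointJunction]
    lesions: pd.DataFrame
    truth: SimTruth


def n_carriers(prevalence: float, cohort_size: int) -> int:
    """Deterministic carrier count: round(prevalence * n), half away from zero."""
    return int(math.floor(prevalence * cohort_size + 0.5))


def _background_cnas(rng: np.random.Generator, genome: dict[str, int],
                     mean_count: float, exclude: str,
                     sample_id: str) -> list[CNSegment]:
    """Disjoint background CNA segments on chromosomes other than ``exclude``."""
    chroms = [c for c in sorted(genome) if c != exclude]
    count = int(rng.poisson(mean_count))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[CNSegment] = []
    attempts = 0
    while count > 0 and attempts < 50 * (count + 1):
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1_000_000, 10_000_001))
        if genome[chrom] <= length:
            continue
        start = int(rng.integers(0, genome[chrom] - length))
        end = start + length
        if any(start < e and end > s for s, e in placed[chrom]):
            continue
        u = rng.random()
        if u < 0.55:
            cn, loh = 1.0, False       # loss
        elif u < 0.90:
            cn, loh = 3.0, False       # gain
        else:
            cn, loh = 2.0, True        # CNN-LOH
        placed[chrom].append((start, end))
        out.append(CNSegment(chrom, start, end, cn, loh, sample_id))
        count -= 1
    return out


def _tile_neutral(genome: dict[str, int], events: list[CNSegment],
                  sample_id: str, skip_chroms: set[str]) -> list[CNSegment]:
    """Fill the rest of the genome with neutral CN-2 segments."""
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in events:
        by_chrom.setdefault(s.chrom, []).append(s)
    out: list[CNSegment] = []
    for chrom, length in sorted(genome.items()):
        if chrom in skip_chroms:
            continue
        pos = 0
        for seg in sorted(by_chrom.get(chrom, []), key=lambda s: s.start):
            if seg.start > pos:
                out.append(CNSegment(chrom, pos, seg.start, 2.0, False, sample_id))
            pos = seg.end
        if pos < length:
            out.append(CNSegment(chrom, pos, length, 2.0, False, sample_id))
    return out


def simulate_cohort(params: SimParams,
                    genome: dict[str, int] | None = None,
                    core: tuple[str, int, int] | None = None,
                    ) -> CohortBundle:
    """Simulate a cohort with a planted recurrent chr21q amplification.

    ``round(prevalence * cohort_size)`` samples carry an amplification event
    (chromothripsis with amplified pieces, or a simple tandem duplication)
    whose gained intervals all contain the designated ``core``; carriers also
    receive more background CNAs than non-carriers, and the lesion table
    couples TP53 status to carrier status.
    """
    rng = _rng(params.seed)
    genome = dict(DEFAULT_GENOME if genome is None else genome)
    core = CHR21_CORE if core is None else core
    if params.cohort_size < 2:
        raise ValueError("cohort_size must be >= 2")
    core_chrom, core_start, core_end = core
    chrom_len = genome[core_chrom]

    n = params.cohort_size
    k = n_carriers(params.chr21amp_prevalence, n)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    carrier_idx = set(rng.choice(n, size=k, replace=False).tolist())

    all_segments: list[CNSegment] = []
    all_junctions: list[BreakpointJunction] = []
    mechanisms: dict[str, str] = {}
    flags: dict[str, bool] = {}
    lesion_rows = []

    for i, sid in enumerate(sample_ids):
        is_carrier = i in carrier_idx
        flags[sid] = is_carrier
        event_segments: list[CNSegment] = []
        covered = {core_chrom} if is_carrier else set()

        if is_carrier:
            ev_start = int(rng.integers(25_000_000, core_start - 500_000))
            ev_end = int(rng.integers(core_end + 500_000, chrom_len - 500_000))
            region = (core_chrom, ev_start, ev_end)
            if rng.random() < params.p_chromothripsis_carrier:
                arr, _ = simulate_chromothripsis(
                    region, params.n_breakpoints, params.retention_prob,
                    rng, genome=genome, amplify_region=core, max_copies=3)
                mechanisms[sid] = "chromothripsis"
            else:
                dup = (core_chrom,
                       int(rng.integers(ev_start, core_start)),
                       int(rng.integers(core_end, ev_end + 1)))
                arr, _ = simulate_simple_duplication(
                    dup, n_copies=int(rng.integers(2, 5)), genome=genome)
                mechanisms[sid] = "simple_sv"
            event_segments = [
                CNSegment(s.chrom, s.start, s.end, s.total_cn, False, sid)
                for s in derive_cn_profile(arr)]
            all_junctions.extend(derive_junctions(
                arr, params.insertion_len_range, rng, sample_id=sid))

        mean = (params.burden_mean_carriers if is_carrier
                else params.burden_mean_noncarriers)
        background = _background_cnas(rng, genome, mean, core_chrom, sid)
        event_segments.extend(background)
        event_segments.extend(
            _tile_neutral(genome, background, sid, skip_chroms=covered))

        event_segments.sort(key=lambda s: (s.chrom, s.start))
        all_segments.extend(event_segments)

        p_tp53 = params.p_tp53_carrier if is_carrier else params.p_tp53_noncarrier
        lesion_rows.append({
            "sample_id": sid,
            "chr21amp": int(is_carrier),
            "JAK2_mut": int(rng.random() < params.p_jak2),
            "TP53_alt": int(rng.random() < p_tp53),
        })

    truth = SimTruth(
        mechanism_label="cohort",
        footprint=[core],
        sample_flags=flags,
        extra={"mechanisms": mechanisms, "core": list(core),
               "n_carriers": k})
    return CohortBundle(
        segments=all_segments,
        junctions=all_junctions,
        lesions=pd.DataFrame(lesion_rows),
        truth=truth)


# ---------------------------------------------------------------------------
# single cells + expression

CLONE_LABELS = ("WT", "JAK2", "JAK2+TP53", "JAK2+TP53+chr21amp")

_CLONE_GENOTYPES = {
    "WT": ("wt", "wt", "normal"),
    "JAK2": ("mutant", "wt", "normal"),
    "JAK2+TP53": ("mutant", "mutant", "normal"),
    "JAK2+TP53+chr21amp": ("mutant", "mutant", "amp"),
}


def _exact_clone_counts(fractions: Sequence[float], n: int) -> np.ndarray:
    """Largest-remainder apportionment; exact when n*fraction is integral."""
    raw = np.asarray(fractions, dtype=float) * n
    base = np.floor(raw + 1e-9).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def simulate_single_cells(params: SimParams,
                          genes: Sequence[str] | None = None,
                          responsive: Sequence[str] | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-cell genotypes, gene counts and allelic read counts.

    Cells are drawn from the linear hierarchy WT -> JAK2 -> JAK2+TP53 ->
    triple with deterministic (largest-remainder) clone counts; genotype
    calls drop out independently with ``ado_rate``.  Counts follow a negative
    binomial whose mean is scaled by ``(CN/2) ** dosage_factor`` for
    dosage-responsive genes in amplified cells.  Allelic SNP reads for
    amplified genes are binomial with success probability ``(CN-1)/CN``
    toward the amplified allele.

    Returns ``(cells, counts, ase)`` data frames.
    """
    rng = _rng(params.seed)
    genes = list(MAR_GENES if genes is None else genes)
    responsive = list(RESPONSIVE_GENES if responsive is None else responsive)
    counts_per_clone = _exact_clone_counts(params.clone_fractions, params.n_cells)

    clone_of_cell: list[str] = []
    for label, c in zip(CLONE_LABELS, counts_per_clone):
        clone_of_cell.extend([label] * int(c))

    rows = []
    is_amp = np.zeros(params.n_cells, dtype=bool)
    for i, clone in enumerate(clone_of_cell):
        jak2, tp53, chr21 = _CLONE_GENOTYPES[clone]
        calls = [jak2, tp53, chr21]
        for k in range(3):
            if rng.random() < params.ado_rate:
                calls[k] = "missing"
        is_amp[i] = clone == CLONE_LABELS[3]
        rows.append({"cell_id": f"c{i:04d}", "donor_id": "D1",
                     "JAK2": calls[0], "TP53": calls[1], "chr21": calls[2],
                     "true_clone": clone})
    cells = pd.DataFrame(rows)

    # expression counts: one fixed baseline mean per gene, dosage shift for
    # responsive genes in amplified cells
    mu0 = rng.lognormal(mean=np.log(5.0), sigma=0.7, size=len(genes))
    scale = (params.amp_cn / 2.0) ** params.dosage_factor
    r = 1.0 / params.nb_dispersion
    mat = np.empty((params.n_cells, len(genes)), dtype=int)
    for g, gene in enumerate(genes):
        mu = np.full(params.n_cells, mu0[g])
        if gene in responsive:
            mu[is_amp] *= scale
        p = r / (r + mu)
        mat[:, g] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(mat, index=cells["cell_id"], columns=genes)

    # allelic reads over amplified cells, pseudobulked per gene/SNP
    f_amp = (params.amp_cn - 1) / params.amp_cn
    ase_rows = []
    for gene in genes:
        for s in range(params.snps_per_gene):
            depth = params.ase_depth
            amp_reads = int(rng.binomial(depth, f_amp))
            ase_rows.append({"gene": gene, "snp_id": f"{gene}_snp{s}",
                             "amp_reads": amp_reads, "total_reads": depth,
                             "total_cn": params.amp_cn})
    ase = pd.DataFrame(ase_rows)
    return cells, counts, ase


# ---------------------------------------------------------------------------
# expression-result fixtures consumed by the prioritization stage

def simulate_bulk_de_table(params: SimParams,
                           genes: Sequence[str] | None = None,
                           ) -> pd.DataFrame:
    """Bulk DE result fixture: the first responsive gene is up, others flat."""
    rng = _rng(params.seed + 1 if isinstance(params.seed, int) else params.seed)
    genes = list(MAR_GENES if genes is None else genes)
    rows = []
    for gene in genes:
        if gene == RESPONSIVE_GENES[0]:
            lfc, p = 1.2 + rng.random() * 0.5, 5e-4
        else:
            lfc, p = rng.normal(0, 0.2), float(min(1.0, 0.2 + rng.random() * 0.8))
        rows.append({"gene": gene, "log2_fc": round(float(lfc), 4),
                     "p": p, "p_adj": min(1.0, p * 10)})
    return pd.DataFrame(rows)


def simulate_da_table(params: SimParams,
                      genes: Sequence[str] | None = None,
                      ) -> pd.DataFrame:
    """DA peak fixture: a significant promoter peak at the first responsive
    gene plus significant gene-body peaks there and at the other responsive
    genes."""
    rng = _rng(params.seed + 2 if isinstance(params.seed, int) else params.seed)
    genes = list(MAR_GENES if genes is None else genes)
    anno = {g: (s, e) for g, _, s, e in
            mar_gene_annotation(genes=genes).itertuples(index=False)}
    rows = []
    lead = RESPONSIVE_GENES[0]
    for gene in genes:
        start, end = anno[gene]
        if gene == lead:
            rows.append({"gene": gene, "chrom": CHR21_CORE[0],
                         "start": start - 1500, "end": start - 500,
                         "is_promoter": 1, "log2_fc": 2.36, "p_adj": 0.015})
            for b in range(6):
                rows.append({"gene": gene, "chrom": CHR21_CORE[0],
                             "start": start + 2000 * (b + 1),
                             "end": start + 2000 * (b + 1) + 500,
                             "is_promoter": 0,
                             "log2_fc": round(1.0 + rng.random(), 3),
                             "p_adj": round(0.001 + rng.random() * 0.04, 5)})
        elif gene in RESPONSIVE_GENES:
            rows.append({"gene": gene, "chrom": CHR21_CORE[0],
                         "start": start + 3000, "end": start + 3500,
                         "is_promoter": 0,
                         "log2_fc": round(0.8 + rng.random(), 3),
                         "p_adj": round(0.005 + rng.random() * 0.04, 5)})
    return pd.DataFrame(rows)


def mar_gene_annotation(genes: Sequence[str] | None = None,
                        core: tuple[str, int, int] | None = None,
                        n_flanking: int = 6) -> pd.DataFrame:
    """Gene annotation: the panel spaced evenly inside the core, plus
    flanking genes outside it (BED-like frame: gene, chrom, start, end)."""
    genes = list(MAR_GENES if genes is None else genes)
    chrom, start, end = CHR21_CORE if core is None else core
    pitch = (end - start) // len(genes)
    glen = max(pitch // 3, 1000)
    rows = [{"gene": g, "chrom": chrom,
             "start": start + i * pitch + pitch // 4,
             "end": start + i * pitch + pitch // 4 + glen}
            for i, g in enumerate(genes)]
    for i in range(n_flanking):
        pos = start - (i + 1) * 400_000
        rows.append({"gene": f"FLANK{i}", "chrom": chrom,
                     "start": pos, "end": pos + 50_000})
    return pd.DataFrame(rows)[["gene", "chrom", "start", "end"]]
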