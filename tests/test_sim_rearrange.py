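import numpy as np
import pandas as pd
import pytest

from shatterkit import sim_rearrange as sr
from shatterkit.sv_io import classify_orientation
from shatterkit.sv_clustering import max_oscillation_run
from shatterkit.clonal_hierarchy import (
    InsufficientDataError, infer_event_order, tabulate_states)

from conftest import TOY_GENOME, per_base_cn_oracle

REGION = ("chr21", 30_000_000, 43_000_000)


class TestChromothripsis:
    def test_identity_case(self):
        arr, _ = sr.simulate_chromothripsis(
            REGION, n_breakpoints=4, retention_prob=1.0, seed=0,
            permutation=range(5), inversions=[False] * 5)
        assert sr.derive_junctions(arr, seed=0) == []
        segs = sr.derive_cn_profile(arr)
        assert len(segs) == 1 and segs[0].total_cn == 2.0

    def test_retention_distribution_binomial(self):
        # n_breakpoints=9 -> 10 pieces kept iid Bernoulli(0.5):
        # counts over 1000 seeds should match Binomial(10, 0.5)
        counts = []
        for seed in range(1000):
            _, truth = sr.simulate_chromothripsis(
                REGION, n_breakpoints=9, retention_prob=0.5, seed=seed)
            counts.append(truth.extra["n_retained"])
        counts = np.asarray(counts)
        assert counts.min() >= 0 and counts.max() <= 10
        # Binomial(10,.5): mean 5, sd ~1.58; sample mean sd ~0.05
        assert abs(counts.mean() - 5.0) < 0.2
        assert abs(counts.std() - np.sqrt(2.5)) < 0.2

    def test_lost_fragments_cause_single_allele_loss(self):
        arr, truth = sr.simulate_chromothripsis(
            REGION, n_breakpoints=9, retention_prob=0.5, seed=1)
        segs = sr.derive_cn_profile(arr)
        if truth.extra["n_retained"] < truth.extra["n_pieces"]:
            assert min(s.total_cn for s in segs) == 1.0  # one allele lost

    def test_cn_oscillation_run_at_default_params(self):
        # default params (20 breakpoints, retention 0.5) oscillate CN
        # between two states with a long run
        for seed in range(10):
            arr, _ = sr.simulate_chromothripsis(REGION, 20, 0.5, seed)
            states = [s.total_cn for s in sr.derive_cn_profile(arr)
                      if s.start >= REGION[1] and s.end <= REGION[2]]
            assert max_oscillation_run(states, 2) >= 4

    def test_degenerate_draw_rejected(self):
        genome = {"chrA": 10_000}
        with pytest.raises(sr.DegenerateDrawError):
            sr.simulate_chromothripsis(("chrA", 0, 10_000), 2, 0.0, seed=0,
                                       genome=genome)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            sr.simulate_chromothripsis(REGION, 1, 0.5, seed=0)
        with pytest.raises(ValueError):
            sr.simulate_chromothripsis(("chr21", 0, 3), 5, 0.5, seed=0)
        with pytest.raises(ValueError):
            sr.simulate_chromothripsis(REGION, 5, 1.5, seed=0)

    def test_seed_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            sr.simulate_chromothripsis(REGION, 5, 0.5, seed=None)

    def test_interchromosomal_mode_emits_translocations(self):
        arr, _ = sr.simulate_chromothripsis(
            REGION, 10, 0.9, seed=3,
            interchrom_region=("chr17", 1_000_000, 2_000_000))
        js = sr.derive_junctions(arr, seed=3)
        assert any(classify_orientation(j) == "TRA" for j in js)


class TestBfb:
    def test_single_cycle_single_foldback(self):
        from shatterkit.event_classify import detect_foldback
        arr, _ = sr.simulate_bfb(("chr21", 38_000_000, 39_000_000), 1, seed=0)
        js = sr.derive_junctions(arr, seed=0)
        assert len(js) == 1
        assert classify_orientation(js[0]) in ("HH", "TT")
        assert detect_foldback(js[0])

    def test_multiplicity_bounded_by_power_of_two(self):
        arr, _ = sr.simulate_bfb(("chr21", 38_000_000, 39_000_000), 3, seed=7)
        from collections import Counter
        mult = Counter((f.chrom, f.start, f.end) for f in arr.fragments)
        assert max(mult.values()) <= 2 ** 3

    def test_max_cn_bound_and_monotone_in_cycles(self):
        region = ("chr21", 38_000_000, 39_000_000)
        prev = 0.0
        for n in range(1, 5):
            arr, _ = sr.simulate_bfb(region, n, seed=11)
            top = max(s.total_cn for s in sr.derive_cn_profile(arr))
            assert top <= 2 ** n + 1
            assert top >= prev  # same seed prefix -> non-decreasing
            prev = top

    def test_too_short_region(self):
        with pytest.raises(ValueError):
            sr.simulate_bfb(("chr21", 100, 101), 1, seed=0)

    def test_foldback_detected_across_seeds(self):
        from shatterkit.event_classify import detect_foldback
        for seed in range(20):
            arr, _ = sr.simulate_bfb(("chr21", 38_000_000, 39_000_000), 2,
                                     seed=seed)
            js = sr.derive_junctions(arr, seed=seed)
            assert any(detect_foldback(j) for j in js)


class TestCnProfile:
    def test_identity_flat(self):
        arr = sr.identity_arrangement(("chrA", 2000, 8000), TOY_GENOME)
        segs = sr.derive_cn_profile(arr)
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end, segs[0].total_cn) == (0, 10_000, 2.0)

    def test_one_fragment_lost(self):
        frags = (sr.Fragment("chrA", 0, 4000), sr.Fragment("chrA", 6000, 10_000))
        arr = sr.DerivativeArrangement(frags, "simple_sv",
                                       (("chrA", 10_000),), ("chrA", 0, 10_000))
        segs = sr.derive_cn_profile(arr)
        assert [(s.start, s.end, s.total_cn) for s in segs] == [
            (0, 4000, 2.0), (4000, 6000, 1.0), (6000, 10_000, 2.0)]

    def test_triple_retention_gives_cn4(self):
        frags = (sr.Fragment("chrA", 0, 2000),
                 sr.Fragment("chrA", 2000, 4000, copy_index=0),
                 sr.Fragment("chrA", 2000, 4000, copy_index=1),
                 sr.Fragment("chrA", 2000, 4000, copy_index=2),
                 sr.Fragment("chrA", 4000, 10_000))
        arr = sr.DerivativeArrangement(frags, "simple_sv",
                                       (("chrA", 10_000),), ("chrA", 0, 10_000))
        segs = {(s.start, s.end): s.total_cn for s in sr.derive_cn_profile(arr)}
        assert segs[(2000, 4000)] == 4.0

    @pytest.mark.parametrize("seed", range(20))
    def test_copy_mass_conservation_chromothripsis(self, seed):
        arr, _ = sr.simulate_chromothripsis(
            ("chrA", 2000, 8000), 5, 0.5, seed, genome=TOY_GENOME,
            amplify_region=("chrA", 4000, 5000) if seed % 2 else None,
            max_copies=3 if seed % 2 else 1)
        self._assert_matches_oracle(arr)

    @pytest.mark.parametrize("seed", range(10))
    def test_copy_mass_conservation_bfb(self, seed):
        arr, _ = sr.simulate_bfb(("chrA", 2000, 8000), 3, seed,
                                 genome=TOY_GENOME)
        self._assert_matches_oracle(arr)

    @staticmethod
    def _assert_matches_oracle(arr, ploidy=2):
        oracle = per_base_cn_oracle(arr, ploidy)
        segs = sr.derive_cn_profile(arr, ploidy)
        for chrom, cov in oracle.items():
            rebuilt = np.empty_like(cov)
            for s in (s for s in segs if s.chrom == chrom):
                rebuilt[s.start:s.end] = int(s.total_cn)
            np.testing.assert_array_equal(rebuilt, cov)
            # copy-mass conservation: sum (CN - ploidy) * len equals net
            # gained minus lost bases from fragment multiplicities
            delta = sum((s.total_cn - ploidy) * s.length
                        for s in segs if s.chrom == chrom)
            assert delta == int((cov - ploidy).sum())


class TestDeriveJunctions:
    def _arr(self, frags):
        return sr.DerivativeArrangement(tuple(frags), "chromothripsis",
                                        (("chrA", 10_000),),
                                        ("chrA", 0, 10_000))

    def test_skipped_fragment_gives_deletion(self):
        arr = self._arr([sr.Fragment("chrA", 0, 100),
                         sr.Fragment("chrA", 200, 300)])
        (j,) = sr.derive_junctions(arr, seed=0)
        assert classify_orientation(j) == "D"
        assert (j.pos1, j.pos2) == (100, 200)

    def test_foldback_is_hh(self):
        arr = self._arr([sr.Fragment("chrA", 0, 100),
                         sr.Fragment("chrA", 0, 100, "-")])
        (j,) = sr.derive_junctions(arr, seed=0)
        assert classify_orientation(j) == "HH"
        assert j.pos1 == j.pos2 == 100

    def test_contiguous_reverse_pair_silent(self):
        # ...b-1..a][a-1..c... reads contiguously when both inverted
        arr = self._arr([sr.Fragment("chrA", 100, 200, "-"),
                         sr.Fragment("chrA", 0, 100, "-")])
        assert sr.derive_junctions(arr, seed=0) == []

    def test_tandem_duplication_dedup(self):
        arr, _ = sr.simulate_simple_duplication(("chrA", 2000, 8000), 4,
                                                genome=TOY_GENOME)
        js = sr.derive_junctions(arr, seed=0)
        assert len(js) == 1
        assert classify_orientation(js[0]) == "TD"
        js_all = sr.derive_junctions(arr, seed=0, deduplicate=False)
        assert len(js_all) == 3

    def test_insertion_length_distribution(self):
        # 10,001 alternating-orientation copies -> 10,000 junctions
        frags = []
        for i in range(10_001):
            frags.append(sr.Fragment("chrA", 1000, 2000,
                                     "+" if i % 2 == 0 else "-", i // 2))
        js = sr.derive_junctions(self._arr(frags), seed=5, deduplicate=False)
        lens = np.array([j.insertion_len for j in js])
        assert len(lens) == 10_000
        assert lens.min() >= 0 and lens.max() <= 6
        assert abs(lens.mean() - 3.0) < 0.06

    def test_orientation_class_diversity_over_events(self):
        seen = set()
        for seed in range(50):
            arr, _ = sr.simulate_chromothripsis(REGION, 20, 0.5, seed)
            seen |= {classify_orientation(j)
                     for j in sr.derive_junctions(arr, seed=seed)}
        assert {"D", "TD", "HH", "TT"} <= seen


class TestSimParams:
    def test_bad_probability(self):
        with pytest.raises(ValueError):
            sr.SimParams(seed=0, ado_rate=1.5)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sr.SimParams(seed=0, clone_fractions=(0.5, 0.5, 0.5, 0.5))

    def test_dispersion_positive(self):
        with pytest.raises(ValueError):
            sr.SimParams(seed=0, nb_dispersion=0.0)


class TestCohort:
    def test_deterministic_carrier_count(self):
        b = sr.simulate_cohort(sr.SimParams(seed=3))
        assert b.truth.extra["n_carriers"] == 16
        assert sum(b.truth.sample_flags.values()) == 16

    def test_carrier_rounding_rule(self):
        assert sr.n_carriers(0.25, 64) == 16
        assert sr.n_carriers(0.25, 62) == 16  # 15.5 rounds half up
        assert sr.n_carriers(0.0, 64) == 0

    def test_zero_prevalence_no_gain_over_target(self):
        p = sr.SimParams(seed=4, chr21amp_prevalence=0.0, cohort_size=10)
        b = sr.simulate_cohort(p)
        chrom, s, e = sr.CHR21_CORE
        for seg in b.segments:
            if seg.chrom == chrom and seg.start < e and seg.end > s:
                assert seg.total_cn < 2.5

    def test_amplified_core_in_every_carrier(self):
        b = sr.simulate_cohort(sr.SimParams(seed=5, cohort_size=16))
        chrom, cs, ce = sr.CHR21_CORE
        for sid, flag in b.truth.sample_flags.items():
            if not flag:
                continue
            cov = [(s.start, s.end) for s in b.segments
                   if s.sample_id == sid and s.chrom == chrom
                   and s.total_cn >= 2.5]
            from shatterkit._intervals import contains
            assert contains(cov, cs, ce)

    def test_burden_separation(self):
        from shatterkit.cn_cohort import count_cna_burden
        b = sr.simulate_cohort(sr.SimParams(seed=6))
        by_sample = {}
        for s in b.segments:
            by_sample.setdefault(s.sample_id, []).append(s)
        carriers, noncarr = [], []
        for sid, segs in by_sample.items():
            (carriers if b.truth.sample_flags[sid] else noncarr).append(
                count_cna_burden(segs, exclude_chrom="chr21"))
        assert np.median(carriers) > np.median(noncarr)

    def test_segments_nonoverlapping_per_sample(self, tmp_path):
        from shatterkit.sv_io import read_segments, write_segments
        b = sr.simulate_cohort(sr.SimParams(seed=7, cohort_size=8))
        p = tmp_path / "segs.tsv"
        write_segments(p, b.segments)
        read_segments(p)  # raises on any within-sample overlap

    def test_cohort_size_precondition(self):
        with pytest.raises(ValueError):
            sr.simulate_cohort(sr.SimParams(seed=0, cohort_size=1))

    def test_determinism(self):
        a = sr.simulate_cohort(sr.SimParams(seed=9, cohort_size=8))
        b = sr.simulate_cohort(sr.SimParams(seed=9, cohort_size=8))
        assert a.segments == b.segments
        assert a.junctions == b.junctions
        pd.testing.assert_frame_equal(a.lesions, b.lesions)


class TestSingleCells:
    def test_exact_state_recovery_without_dropout(self):
        params = sr.SimParams(seed=5, ado_rate=0.0)
        cells, _, _ = sr.simulate_single_cells(params)
        sc = tabulate_states(cells)
        assert sc.counts == {"WT": 107, "JAK2": 179, "JAK2+TP53": 162,
                             "JAK2+TP53+chr21amp": 1455}
        assert sc.n_usable == 1903 and sc.n_unusable == 0

    def test_full_dropout_signals_insufficient_data(self):
        params = sr.SimParams(seed=5, ado_rate=1.0, n_cells=50)
        cells, _, _ = sr.simulate_single_cells(params)
        with pytest.raises(InsufficientDataError):
            infer_event_order(cells)

    def test_ase_mean_fraction_matches_dosage(self):
        # CN 3 -> expected amplified-allele fraction 2/3 over ~1000 draws
        params = sr.SimParams(seed=8, snps_per_gene=42, ase_depth=30)
        _, _, ase = sr.simulate_single_cells(params)
        assert len(ase) == 24 * 42
        frac = ase.amp_reads.sum() / ase.total_reads.sum()
        assert abs(frac - 2 / 3) < 0.02

    def test_counts_shape_and_determinism(self):
        params = sr.SimParams(seed=10, n_cells=100)
        cells_a, counts_a, ase_a = sr.simulate_single_cells(params)
        cells_b, counts_b, ase_b = sr.simulate_single_cells(params)
        assert counts_a.shape == (100, 24)
        pd.testing.assert_frame_equal(cells_a, cells_b)
        pd.testing.assert_frame_equal(counts_a, counts_b)
        pd.testing.assert_frame_equal(ase_a, ase_b)

    def test_dosage_shift_only_on_responsive_genes(self):
        params = sr.SimParams(seed=11, ado_rate=0.0, n_cells=2000,
                              clone_fractions=(0.5, 0.0, 0.0, 0.5))
        cells, counts, _ = sr.simulate_single_cells(params)
        amp = (cells.set_index("cell_id")["chr21"] == "amp").to_numpy()
        for gene in sr.RESPONSIVE_GENES:
            assert counts.loc[amp, gene].mean() > 1.2 * counts.loc[~amp, gene].mean()
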