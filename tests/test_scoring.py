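import itertools
import math

import numpy as np
import pytest

from shiftassign.peak_io import AtomId
from shiftassign.problem_model import NONE
from shiftassign.scoring import (
    ScoringConfig,
    alignment_Q2,
    degeneracy_b,
    get_evaluator,
    global_score_G,
    objective_vector,
    shift_normality_Q1,
)
from shiftassign.peak_io import ValidationError
from conftest import random_tiny_instance
from oracles import brute_degeneracy, brute_global_score, brute_objectives

EXP_HALF = math.exp(-0.5)


class TestKernels:
    def test_q1_maximal_at_the_mean(self, one_gene_instance):
        assert shift_normality_Q1(one_gene_instance, AtomId("H", 1), 8.0) == 1.0

    def test_q1_one_sigma_away(self, one_gene_instance):
        assert shift_normality_Q1(one_gene_instance, AtomId("H", 1), 8.5) == pytest.approx(EXP_HALF)

    def test_q1_symmetric(self, one_gene_instance):
        lo = shift_normality_Q1(one_gene_instance, AtomId("H", 1), 7.5)
        hi = shift_normality_Q1(one_gene_instance, AtomId("H", 1), 8.5)
        assert lo == pytest.approx(hi)

    def test_q1_zero_without_statistics(self, tiny_instance):
        # no (ALA, HB) entry in the fixture statistics
        assert shift_normality_Q1(tiny_instance, AtomId("HB", 1), 1.5) == 0.0

    def test_q2_maximal_at_the_mean(self, one_gene_instance):
        assert alignment_Q2(one_gene_instance, AtomId("H", 1), 8.1, 8.1) == 1.0

    def test_q2_one_tolerance_away(self, one_gene_instance):
        q = alignment_Q2(one_gene_instance, AtomId("H", 1), 8.13, 8.10)
        assert q == pytest.approx(EXP_HALF)

    def test_q2_nucleus_specific_tolerance(self, tiny_instance):
        # carbon tolerance 0.4: a 0.4 ppm offset scores exp(-1/2)
        q = alignment_Q2(tiny_instance, AtomId("CA", 1), 53.4, 53.0)
        assert q == pytest.approx(EXP_HALF)


class TestDegeneracy:
    def test_uniquely_mapped_gene(self, tiny_instance):
        chrom = np.array([0, 1, 0])
        assert degeneracy_b(tiny_instance, chrom, 0) == 1

    def test_two_expected_on_one_measured(self, tiny_instance):
        chrom = np.array([0, 0, NONE])
        assert degeneracy_b(tiny_instance, chrom, 0) == 2
        assert degeneracy_b(tiny_instance, chrom, 1) == 2

    def test_unmapped_gene_is_a_contract_violation(self, tiny_instance):
        with pytest.raises(ValidationError):
            degeneracy_b(tiny_instance, tiny_instance.empty_chromosome(), 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_tiny_instance(rng)
        chrom = inst.random_chromosome(rng)
        for g in range(inst.L):
            if chrom[g] != NONE:
                assert degeneracy_b(inst, chrom, g) == brute_degeneracy(inst, chrom, g)


class TestObjectiveVector:
    def test_all_none_is_zero(self, tiny_instance):
        assert objective_vector(tiny_instance, tiny_instance.empty_chromosome()) == (
            0.0, 0.0, 0.0, 0.0,
        )

    def test_single_perfect_2d_gene(self, one_gene_instance):
        chrom = np.array([1])  # measured peak at the statistical means
        F = objective_vector(one_gene_instance, chrom)
        assert F.F1 == pytest.approx(-2.0)
        assert F.F2 == pytest.approx(-2.0)
        assert F.F3 == -2.0
        assert F.F4 == 2.0

    def test_spectrum_relabeling_invariance(self, tiny_instance):
        chrom = np.array([1, 0, 0])
        before = objective_vector(tiny_instance, chrom)
        renamed = {"HSQC": "A", "HNCA": "B"}
        from shiftassign.peak_io import ExpectedPeak, MeasuredPeak, SpectrumDefinition
        from shiftassign.problem_model import build_instance

        spectra = [
            SpectrumDefinition(name=renamed[s.name], dimensions=s.dimensions)
            for s in tiny_instance.spectra
        ]
        expected = {
            renamed[k]: [
                ExpectedPeak(p.peak_id, renamed[k], p.atoms) for p in v
            ]
            for k, v in tiny_instance.expected.items()
        }
        measured = {
            renamed[k]: [
                MeasuredPeak(p.peak_id, renamed[k], p.position) for p in v
            ]
            for k, v in tiny_instance.measured.items()
        }
        other = build_instance(
            tiny_instance.sequence, spectra, expected, measured,
            tiny_instance.statistics, tiny_instance.tolerances,
        )
        assert objective_vector(other, chrom) == pytest.approx(tuple(before))


class TestGlobalScore:
    def test_all_none_scores_zero(self, tiny_instance):
        assert global_score_G(tiny_instance, tiny_instance.empty_chromosome()) == 0.0

    def test_perfect_complete_assignment_scores_one(self, tiny_instance):
        # measured peaks sit exactly at the statistical means and each atom's
        # contributions agree, so Q1 = Q2 = 1 and b = 1 everywhere
        chrom = np.array([0, 1, 0])
        assert global_score_G(tiny_instance, chrom) == pytest.approx(1.0)

    def test_default_weights_are_4_and_1(self, one_gene_instance):
        chrom = np.array([1])
        default = global_score_G(one_gene_instance, chrom)
        explicit = global_score_G(one_gene_instance, chrom, ScoringConfig(w1=4, w2=1))
        assert default == explicit == pytest.approx(1.0)

    def test_adding_fresh_gene_at_means_never_decreases_G(self, tiny_instance):
        partial = np.array([0, NONE, NONE], dtype=np.int64)
        fuller = np.array([0, 1, NONE], dtype=np.int64)
        assert global_score_G(tiny_instance, fuller) >= global_score_G(
            tiny_instance, partial
        )

    def test_empty_instance_is_an_error(self, stats_small, two_residue_sequence):
        from shiftassign.peak_io import SpectrumDefinition
        from shiftassign.problem_model import build_instance

        spec = SpectrumDefinition(name="S", dimensions=(("H", "H"), ("N", "N")))
        inst = build_instance(
            two_residue_sequence, [spec], {"S": []}, {"S": []}, stats_small
        )
        with pytest.raises(ValidationError):
            global_score_G(inst, inst.empty_chromosome())


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_fuzzed_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        inst = random_tiny_instance(rng)
        for _ in range(5):
            chrom = inst.random_chromosome(rng)
            F = objective_vector(inst, chrom)
            G = global_score_G(inst, chrom)
            assert F == pytest.approx(brute_objectives(inst, chrom), abs=1e-9)
            assert G == pytest.approx(brute_global_score(inst, chrom), abs=1e-9)

    def test_incremental_equals_full_recomputation(self):
        rng = np.random.default_rng(77)
        inst = random_tiny_instance(rng)
        chrom = inst.random_chromosome(rng)
        for _ in range(10):
            g = int(rng.integers(inst.L))
            chrom[g] = rng.integers(-1, inst.gene_measured_count[g])
            fresh = inst.random_chromosome(rng)
            fresh[:] = chrom
            assert objective_vector(inst, chrom) == objective_vector(inst, fresh)

    def test_exhaustive_enumeration_small_instance(self, one_gene_instance):
        inst = one_gene_instance
        evaluator = get_evaluator(inst)
        best = None
        for values in itertools.product(range(-1, 2), repeat=inst.L):
            chrom = np.array(values, dtype=np.int64)
            _, g = evaluator.evaluate(chrom)
            assert g == pytest.approx(brute_global_score(inst, chrom), abs=1e-12)
            if best is None or g > best[0]:
                best = (g, values)
        assert best[1] == (1,)  # the measured peak at the means wins
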