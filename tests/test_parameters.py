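"""The four whole-genome descriptors."""

from math import atan, pi

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import TR0_DINUCS, TRCG_DINUCS, dinucleotide_fraction, random_acgt
from wgp import (
    AcpSettings,
    CumulatedPhase,
    a_cp,
    compute_parameters,
    diff_p,
    generate_genome,
    mutate_genome,
    phase_signal,
    rotate_genome,
    tr_0,
    tr_cg,
)


class TestDiffP:
    def test_worked_examples(self):
        """The same base content in a different order changes the value."""
        assert diff_p(phase_signal("AAAGGG")) == pytest.approx(pi / 2 / 6, abs=1e-12)
        assert diff_p(phase_signal("AGAGAG")) == pytest.approx(5 * pi / 2 / 6, abs=1e-12)
        assert round(diff_p(phase_signal("AAAGGG")), 2) == 0.26
        assert round(diff_p(phase_signal("AGAGAG")), 2) == 1.31

    def test_constant_signal_is_zero(self):
        assert diff_p(phase_signal("AAAA")) == 0.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            diff_p(phase_signal("A"))

    def test_upper_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = random_acgt(rng, 50)
            L = len(seq)
            assert 0 <= diff_p(phase_signal(seq)) <= 3 * pi / 2 * (L - 1) / L + 1e-12


class TestTransitions:
    def test_worked_example(self):
        phase = phase_signal("CAGGCAG")
        assert tr_0(phase) == pytest.approx(3 / 6)
        assert tr_cg(phase) == pytest.approx(2 / 6)

    @pytest.mark.parametrize(
        "fn, seq, expected",
        [
            (tr_0, "AAAA", 0.0),
            (tr_0, "ACAC", 1.0),
            (tr_cg, "ATAT", 0.0),
            (tr_cg, "GCGC", 1.0),
        ],
    )
    def test_edge_examples(self, fn, seq, expected):
        assert fn(phase_signal(seq)) == expected

    def test_zero_phases_are_not_transitions(self):
        # N is neither positive nor negative; W maps to 0 as well
        assert tr_0(phase_signal("ANC")) == 0.0
        assert tr_0(phase_signal("AWC")) == 0.0
        assert tr_cg(phase_signal("GNC")) == 0.0

    @settings(max_examples=150, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=200))
    def test_equal_symbolic_dinucleotide_counting(self, seq):
        """Phase-domain counts equal brute-force dinucleotide counts exactly."""
        phase = phase_signal(seq)
        assert tr_0(phase) == dinucleotide_fraction(seq, TR0_DINUCS)
        assert tr_cg(phase) == dinucleotide_fraction(seq, TRCG_DINUCS)

    def test_composition_expectation(self):
        """For i.i.d. genomes tr_cg -> g^2 and tr_0 -> 2(pA+pG)(pC+pT)."""
        comp = (0.3, 0.2, 0.3, 0.2)  # pA pC pG pT
        L = 1_000_000
        seq = generate_genome(L, comp, seed=42)
        phase = phase_signal(seq)
        g = comp[1] + comp[2]
        q = comp[0] + comp[2]
        se_cg = np.sqrt(g * g * (1 - g * g) / (L - 1))
        se_0 = np.sqrt(2 * q * (1 - q) * (1 - 2 * q * (1 - q)) / (L - 1))
        assert abs(tr_cg(phase) - g * g) < 3 * se_cg
        assert abs(tr_0(phase) - 2 * q * (1 - q)) < 3 * se_0


class TestAcp:
    def test_linear_ramp_slope_one(self):
        sig = CumulatedPhase(np.arange(1.0, 101.0))
        assert sig.i_max == 100
        assert a_cp(sig) == pytest.approx(atan(1.0), abs=1e-12)

    def test_linear_ramp_slope_two(self):
        sig = CumulatedPhase(2.0 * np.arange(1.0, 51.0))
        assert a_cp(sig) == pytest.approx(atan(2.0), abs=1e-12)

    def test_flat_signal_with_forced_maximum(self):
        sig = CumulatedPhase(np.zeros(200), argmax=199)
        assert a_cp(sig) == 0.0

    def test_sampled_indices_round_to_nearest(self):
        # i_max = 24, N = 10: i = round(k*2.4) = 2,5,7,10,12,14,17,19,22,24
        values = np.zeros(24)
        values[1] = 6.0  # read by the i=2 sample: atan(6/2)
        sig = CumulatedPhase(values, argmax=23)
        # every other sampled position reads 0
        assert a_cp(sig) == pytest.approx(atan(3.0) / 10, abs=1e-12)

    def test_maximum_before_n_positions_rejected(self):
        with pytest.raises(ValueError, match="n_positions"):
            a_cp(CumulatedPhase(np.array([5.0, 1.0, 0.0])))
        # a smaller N makes the same signal acceptable
        assert a_cp(CumulatedPhase(np.array([5.0, 1.0, 0.0])), AcpSettings(1)) == pytest.approx(
            atan(5.0)
        )

    def test_result_within_quarter_turn(self):
        rng = np.random.default_rng(1)
        walk = np.cumsum(rng.normal(size=5000))
        walk -= walk.min()
        val = a_cp(CumulatedPhase(walk))
        assert -pi / 2 < val < pi / 2


class TestComputeParameters:
    def test_deterministic(self):
        seq = generate_genome(5000, (0.3, 0.2, 0.3, 0.2), seed=7)
        assert compute_parameters(seq, genome_id="a") == compute_parameters(seq, genome_id="a")

    def test_rotation_yields_identical_a_cp_and_close_transitions(self):
        # zero-net-skew arrow genome: the canonical start is well-posed
        from wgp import gc_skew_ramp_genome

        seq = gc_skew_ramp_genome(50_000, seed=8, gc=0.5, skew=0.06)
        p0 = compute_parameters(seq, genome_id="x")
        p1 = compute_parameters(rotate_genome(seq, 1000), genome_id="x")
        L = len(seq)
        assert p1.a_cp == p0.a_cp
        assert abs(p1.tr_0 - p0.tr_0) <= 2 / (L - 1)
        assert abs(p1.tr_cg - p0.tr_cg) <= 2 / (L - 1)

    def test_periodic_sequence_limits(self):
        """Repeated CAGGCAG: the block-junction G|C pair is both a zero
        crossing and a CG pair, so tr_0 -> 4/7 and tr_cg -> 3/7."""
        seq = "CAGGCAG" * 400
        p = compute_parameters(seq, genome_id="rep")
        assert p.tr_0 == pytest.approx(4 / 7, abs=1e-3)
        assert p.tr_cg == pytest.approx(3 / 7, abs=1e-3)

    def test_order_sensitivity_of_diff_p(self):
        assert diff_p(phase_signal("AAAGGG")) != diff_p(phase_signal("AGAGAG"))

    def test_mutation_continuity(self):
        """1% substitutions move every descriptor only slightly."""
        seq = generate_genome(200_000, (0.33, 0.20, 0.28, 0.19), seed=9)
        mut = mutate_genome(seq, 0.01, seed=10)
        p0 = compute_parameters(seq, genome_id="a")
        p1 = compute_parameters(mut, genome_id="b")
        assert abs(p0.tr_0 - p1.tr_0) < 0.01
        assert abs(p0.tr_cg - p1.tr_cg) < 0.01
        assert abs(p0.diff_p - p1.diff_p) < 0.05
        assert abs(p0.a_cp - p1.a_cp) < 0.05

    def test_rearrangement_opt_out(self):
        seq = rotate_genome(generate_genome(20_000, (0.32, 0.22, 0.32, 0.14), seed=11), 7000)
        with_rot = compute_parameters(seq, genome_id="a")
        without = compute_parameters(seq, genome_id="a", rearrangement=False)
        assert with_rot != without

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            compute_parameters("ACGTA", genome_id="tiny")
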