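"""Usefulness-criterion predictions against exact enumeration and simulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bridgesim.genome import GenomeDefinition
from bridgesim.meiosis import _phase_matrix, recombination_fraction
from bridgesim.trait import true_breeding_values
from bridgesim.ucpc import (
    CrossPredictor,
    DiversityTrajectory,
    expected_diversity,
    he_constraint,
    predict_cross_mean,
    predict_cross_variance,
    selected_fraction_profile,
    selection_intensity,
)
from tests.test_meiosis import two_locus_genome

# pilot-established normal-approximation error bounds for truncation at 5%
UC_APPROX_BOUND_SIGMA = 0.15        # on the selected-fraction mean, in sigma_c units
CONTRIB_APPROX_BOUND = 0.03         # on the expected parental contribution


def enumerate_dh_distribution(h1, h2, genome, effects):
    """Exact DH gamete value distribution via the Markov phase chain.

    Independent oracle for predict_cross_variance: enumerates every phase
    assignment at the segregating loci with its exact probability (switch
    probability between adjacent loci = Haldane recombination fraction).
    """
    h1 = np.asarray(h1, dtype=np.int64)
    h2 = np.asarray(h2, dtype=np.int64)
    seg = np.flatnonzero(h1 != h2)
    assert seg.size <= 12, "enumeration oracle limited to 12 segregating loci"
    chrom, pos = genome.chromosome, genome.position_cm
    base_val = 2.0 * np.asarray(h1, float) @ effects
    vals, probs = [], []
    for phases in itertools.product((0, 1), repeat=seg.size):
        pr = 1.0
        last = {}
        val = base_val
        for locus, ph in zip(seg, phases):
            c = chrom[locus]
            if c in last:
                pl, pph = last[c]
                cc = recombination_fraction(pos[locus] - pos[pl])
                pr *= cc if ph != pph else 1 - cc
            else:
                pr *= 0.5
            last[c] = (locus, ph)
            if ph == 1:
                val += 2.0 * effects[locus] * (h2[locus] - h1[locus])
        vals.append(val)
        probs.append(pr)
    vals, probs = np.array(vals), np.array(probs)
    mean = vals @ probs
    return mean, probs @ (vals - mean) ** 2


class TestSelectionIntensity:
    @pytest.mark.parametrize("p,expected", [(0.05, 2.0627), (0.10, 1.7550), (1.0, 0.0)])
    def test_standard_normal_values(self, p, expected):
        assert selection_intensity(p) == pytest.approx(expected, abs=1e-4)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            selection_intensity(0.0)


class TestCrossMoments:
    def test_mean_is_parental_average(self):
        assert predict_cross_mean(10.0, 20.0) == 15.0
        assert predict_cross_mean(7.0, 7.0) == 7.0

    def test_monomorphic_cross_zero_variance(self, small_genome):
        h = np.ones(small_genome.n_loci, dtype=np.uint8)
        eff = np.zeros(small_genome.n_loci)
        eff[small_genome.qtl_indices] = small_genome.qtl_effects
        assert predict_cross_variance(h, h, eff, small_genome,
                                      np.arange(small_genome.n_loci)) == 0.0

    def test_single_locus_variance_is_beta_squared(self):
        g = two_locus_genome(10.0, effects=(0.7, 0.4))
        h1 = np.array([1, 0], dtype=np.uint8)
        h2 = np.array([0, 0], dtype=np.uint8)  # only locus 0 segregates
        v = predict_cross_variance(h1, h2, np.array([0.7, 0.4]), g, np.array([0, 1]))
        assert v == pytest.approx(0.7 ** 2)

    def test_two_coupled_loci_quarter_recombination(self):
        # 1 - 2c = 0.5  =>  d = 50 ln 2 cM, c = 0.25
        d = 50.0 * np.log(2.0)
        g = two_locus_genome(d)
        h1 = np.array([1, 1], dtype=np.uint8)
        h2 = np.array([0, 0], dtype=np.uint8)
        v = predict_cross_variance(h1, h2, np.array([1.0, 1.0]), g, np.array([0, 1]))
        assert v == pytest.approx(3.0)
        mean, var = enumerate_dh_distribution(h1, h2, g, np.array([1.0, 1.0]))
        assert mean == pytest.approx(2.0)
        assert var == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_variance_equals_exhaustive_enumeration(self, micro_genome, seed):
        rng = np.random.default_rng(seed)
        eff = np.zeros(micro_genome.n_loci)
        eff[micro_genome.qtl_indices] = micro_genome.qtl_effects
        h1 = rng.integers(0, 2, micro_genome.n_loci).astype(np.uint8)
        h2 = rng.integers(0, 2, micro_genome.n_loci).astype(np.uint8)
        v = predict_cross_variance(h1, h2, eff, micro_genome,
                                   np.arange(micro_genome.n_loci))
        _, var = enumerate_dh_distribution(h1, h2, micro_genome, eff)
        assert v == pytest.approx(var, rel=1e-9)


class TestSelectedFraction:
    def _predictor(self, genome):
        return CrossPredictor(genome, genome.qtl_effects, loci=genome.qtl_indices)

    def test_zero_intensity_profile(self, small_genome, rng):
        pred = self._predictor(small_genome)
        h1 = rng.integers(0, 2, small_genome.n_loci).astype(np.uint8)
        h2 = rng.integers(0, 2, small_genome.n_loci).astype(np.uint8)
        prof = selected_fraction_profile(h1, h2, 3.0, 5.0, i=0.0, predictor=pred)
        assert prof.uc == prof.mu == 4.0
        assert prof.contributions == (0.5, 0.5)

    def test_uc_exceeds_mean_for_segregating_cross(self, small_genome, rng):
        pred = self._predictor(small_genome)
        h1 = rng.integers(0, 2, small_genome.n_loci).astype(np.uint8)
        h2 = 1 - h1
        prof = selected_fraction_profile(h1, h2, 5.0, 5.0,
                                         i=selection_intensity(0.05), predictor=pred)
        assert prof.sigma > 0
        assert prof.uc > prof.mu

    def test_monte_carlo_selection_oracle(self, small_genome):
        """Top-5% of 10,000 phase-tracked DH: realized mean, parent-1 genome
        share and allele frequencies match the normal-approximation
        predictions within Monte-Carlo error plus the pilot bounds."""
        rng = np.random.default_rng(11)
        h1 = rng.integers(0, 2, small_genome.n_loci).astype(np.uint8)
        h2 = rng.integers(0, 2, small_genome.n_loci).astype(np.uint8)
        pred = self._predictor(small_genome)
        i = selection_intensity(0.05)
        prof = selected_fraction_profile(
            h1, h2, true_breeding_values(h1, small_genome),
            true_breeding_values(h2, small_genome), i, pred)

        n, keep = 10_000, 500
        phase = _phase_matrix(small_genome, n, rng)
        fam = np.where(phase == 0, h1[None, :], h2[None, :]).astype(np.uint8)
        tbv = true_breeding_values(fam, small_genome)
        sel = np.argsort(tbv)[::-1][:keep]

        sel_mean = tbv[sel].mean()
        se_mean = tbv[sel].std(ddof=1) / np.sqrt(keep)
        assert abs(prof.uc - sel_mean) <= 3 * se_mean + UC_APPROX_BOUND_SIGMA * prof.sigma

        share = (phase[sel][:, small_genome.qtl_indices] == 0).mean(axis=1)
        se_share = share.std(ddof=1) / np.sqrt(keep)
        assert abs(prof.contributions[0] - share.mean()) <= (
            3 * se_share + CONTRIB_APPROX_BOUND)

        seg = h1[small_genome.qtl_indices] != h2[small_genome.qtl_indices]
        freq_real = fam[sel][:, small_genome.qtl_indices].mean(axis=0)
        rmse = np.sqrt(np.mean((prof.selected_freqs[seg] - freq_real[seg]) ** 2))
        assert rmse < 0.08
        assert np.corrcoef(prof.selected_freqs[seg], freq_real[seg])[0, 1] > 0.9

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_profile_invariants(self, micro_genome, seed):
        rng = np.random.default_rng(seed)
        pred = CrossPredictor(micro_genome, micro_genome.qtl_effects,
                              loci=micro_genome.qtl_indices)
        h1 = rng.integers(0, 2, micro_genome.n_loci).astype(np.uint8)
        h2 = rng.integers(0, 2, micro_genome.n_loci).astype(np.uint8)
        i = float(rng.uniform(0, 3))
        prof = selected_fraction_profile(h1, h2, rng.normal(), rng.normal(), i, pred)
        assert prof.sigma >= 0
        assert prof.uc >= prof.mu
        assert 0 <= prof.contributions[0] <= 1
        assert prof.contributions[0] + prof.contributions[1] == pytest.approx(1)
        assert (prof.selected_freqs >= 0).all() and (prof.selected_freqs <= 1).all()


class TestExpectedDiversity:
    def test_identical_parents_zero(self):
        freqs = np.zeros((3, 10))
        assert expected_diversity(freqs) == 0.0

    def test_half_frequencies_maximal(self):
        assert expected_diversity(np.full((2, 10), 0.5)) == pytest.approx(0.5)

    def test_heterotic_cross_unselected(self, small_genome, rng):
        h1 = rng.integers(0, 2, small_genome.n_loci).astype(np.uint8)
        h2 = 1 - h1  # fully heterotic: every locus segregates
        pred = CrossPredictor(small_genome, small_genome.qtl_effects,
                              loci=small_genome.qtl_indices)
        prof = selected_fraction_profile(h1, h2, 0.0, 0.0, i=0.0, predictor=pred)
        assert expected_diversity(prof.selected_freqs[None, :]) == pytest.approx(0.5)

    def test_selection_does_not_create_diversity(self, small_genome, rng):
        """With symmetric contributions, the selected-fraction He of a plan
        never exceeds its unselected (i = 0) expectation."""
        pred = CrossPredictor(small_genome, small_genome.qtl_effects,
                              loci=small_genome.qtl_indices)
        h = rng.integers(0, 2, (8, small_genome.n_loci)).astype(np.uint8)
        pairs = [(a, b) for a in range(8) for b in range(a + 1, 8)]
        sel = np.array(pairs)
        loci = small_genome.qtl_indices
        for i_val in (0.0, selection_intensity(0.05)):
            out = pred.evaluate(h[sel[:, 0]][:, loci], h[sel[:, 1]][:, loci],
                                np.zeros(len(sel)), np.zeros(len(sel)), i=i_val)
            if i_val == 0.0:
                d0 = expected_diversity(out["selected_freqs"])
            else:
                dsel = expected_diversity(out["selected_freqs"])
        assert dsel <= d0 + 1e-9


class TestDiversityTrajectory:
    def test_endpoints_and_interpolation(self):
        traj = DiversityTrajectory(he0=0.133, he_star=0.01, t_star=60)
        assert he_constraint(0, traj) == pytest.approx(0.133)
        assert he_constraint(60, traj) == pytest.approx(0.01)
        assert he_constraint(75, traj) == pytest.approx(0.01)
        assert he_constraint(30, traj) == pytest.approx(0.0715)

    def test_constant_trajectory(self):
        traj = DiversityTrajectory.constant(0.1)
        assert traj.at(0) == traj.at(50) == 0.1
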