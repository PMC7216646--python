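"""Evaluation metrics, distances, and the TS composition experiment."""

import numpy as np
import pandas as pd
import pytest

from bridgesim.genome import expected_heterozygosity
from bridgesim.meiosis import dh_gametes
from bridgesim.metrics import (
    compute_metrics,
    favorable_allele_frequencies,
    modified_rogers_distance,
    pcoa,
    rare_favorable_mask,
    summarize,
    table2_designs,
    ts_composition_experiment,
)
from bridgesim.population import Population
from bridgesim.trait import TraitModel, phenotype, true_breeding_values


def test_mu_and_mu10_arithmetic(small_genome, rng):
    # population with known TBVs is awkward; check the statistics directly on
    # a random population against a direct recomputation
    hap = rng.integers(0, 2, (40, small_genome.n_loci)).astype(np.uint8)
    pop = Population.from_haplotypes(hap, family=np.repeat([0, 1], 20))
    rare = rare_favorable_mask(hap, small_genome)
    m = compute_metrics(pop, small_genome, rare)
    tbv = true_breeding_values(hap, small_genome)
    assert m["mu"] == pytest.approx(tbv.mean())
    assert m["mu10"] == pytest.approx(np.sort(tbv)[-10:].mean())
    assert m["mu10"] >= m["mu"]
    assert 0 <= m["he"] <= 0.5


def test_rare_favorable_bookkeeping(small_genome):
    # all favorable alleles fixed -> frequencies 1, nothing is rare
    full = np.zeros((5, small_genome.n_loci), dtype=np.uint8)
    full[:, small_genome.qtl_indices] = small_genome.favorable_allele
    freqs = favorable_allele_frequencies(full, small_genome)
    assert np.allclose(freqs, 1.0)
    assert not rare_favorable_mask(full, small_genome).any()


def test_he_second_implementation(small_genome, rng):
    hap = rng.integers(0, 2, (60, small_genome.n_loci)).astype(np.uint8)
    pop = Population.from_haplotypes(hap)
    m = compute_metrics(pop, small_genome, np.zeros(133, bool))
    p = hap[:, small_genome.marker_indices].mean(axis=0)
    slow = np.mean([2 * q * (1 - q) for q in p])
    assert m["he"] == pytest.approx(slow)
    assert expected_heterozygosity(p) == pytest.approx(slow)


class TestModifiedRogers:
    def test_limits(self):
        a = np.array([[0, 0, 0, 0]], dtype=np.uint8)
        b = np.array([[1, 1, 1, 1]], dtype=np.uint8)
        half = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        assert modified_rogers_distance(a, a)[0, 0] == 0.0
        assert modified_rogers_distance(a, b)[0, 0] == 1.0
        assert modified_rogers_distance(a, half)[0, 0] == pytest.approx(np.sqrt(0.5))

    def test_pairwise_symmetric_bounded(self, rng):
        hap = rng.integers(0, 2, (12, 50)).astype(np.uint8)
        d = modified_rogers_distance(hap)
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0)

    def test_pcoa_separates_groups(self, rng):
        g1 = np.tile([0] * 30, (8, 1)).astype(np.uint8)
        g2 = np.tile([1] * 30, (8, 1)).astype(np.uint8)
        noise = rng.integers(0, 2, (16, 10)).astype(np.uint8)
        hap = np.hstack([np.vstack([g1, g2]), noise])
        coords, vals = pcoa(modified_rogers_distance(hap))
        assert vals[0] > 0
        side = coords[:8, 0].mean(), coords[8:, 0].mean()
        assert np.sign(side[0]) != np.sign(side[1])


def test_population_roundtrip_bit_identical(small_genome, rng):
    hap = rng.integers(0, 2, (10, small_genome.n_loci)).astype(np.uint8)
    pop = Population.from_haplotypes(hap, family=np.arange(10) // 5, year=2,
                                     program="DE")
    df = pop.to_table()
    back = Population.from_table(pd.read_csv(__import__("io").StringIO(
        df.to_csv(index=False))))
    assert np.array_equal(back.haplotypes, pop.haplotypes)
    rare = rare_favorable_mask(hap, small_genome)
    m1 = compute_metrics(pop, small_genome, rare)
    m2 = compute_metrics(back, small_genome, rare)
    for k in m1:
        assert m2[k] == pytest.approx(m1[k], nan_ok=True, abs=0)


class TestTable2Designs:
    def test_reference_scale_rows(self):
        designs = dict((n, (e, d)) for n, e, d in table2_designs(3600, 1200))
        assert designs["1/6 - DE (3600)"] == (3000, 600)
        assert designs["Pure E (3600)"] == (3600, 0)
        assert designs["1/4 - DE (4800)"] == (3600, 1200)
        assert designs["1/4 - DE (1200)"] == (900, 300)

    def test_scaled_counts_sum_consistently(self):
        for name, ne, nde in table2_designs(900, 300):
            assert 0 <= ne <= 900 and 0 <= nde <= 300
        scaled = dict((n, (e, d)) for n, e, d in table2_designs(900, 300))
        assert scaled["1/6 - DE (3600)"] == (750, 150)


@pytest.fixture(scope="module")
def bridging_snapshot(small_genome):
    """Synthetic snapshot of E and DE progeny pools with phenotypes.

    Elite families come from a narrow set of related lines; bridging (DE)
    families from donor x elite crosses with donors drawn from a diverged
    population, mimicking the structure the experiment operates on.
    """
    g = small_genome
    rng = np.random.default_rng(21)
    elite_base = (rng.random(g.n_loci) < 0.8).astype(np.uint8)
    elites = np.array([np.where(rng.random(g.n_loci) < 0.1,
                                1 - elite_base, elite_base) for _ in range(8)],
                      dtype=np.uint8)
    donors = rng.integers(0, 2, (4, g.n_loci)).astype(np.uint8)
    e_pops, de_pops = [], []
    fam = 0
    for _ in range(12):
        i, j = rng.choice(8, 2, replace=False)
        e_pops.append(Population.from_haplotypes(
            dh_gametes(elites[i], elites[j], g, 30, rng), family=fam)); fam += 1
    for _ in range(6):
        d = rng.integers(4); e = rng.integers(8)
        de_pops.append(Population.from_haplotypes(
            dh_gametes(donors[d], elites[e], g, 30, rng), family=fam,
            program="DE")); fam += 1
    e_pop, de_pop = Population.concat(e_pops), Population.concat(de_pops)
    model = TraitModel.calibrated(np.vstack([elites, donors]), g, 0.4, 4)
    e_phen = phenotype(e_pop.haplotypes, model, rng)
    de_phen = phenotype(de_pop.haplotypes, model, rng)
    return e_pop, e_phen, de_pop, de_phen, model


def test_ts_experiment_design_bookkeeping(bridging_snapshot, small_genome):
    e_pop, e_phen, de_pop, de_phen, model = bridging_snapshot
    rng = np.random.default_rng(5)
    with pytest.raises(ValueError, match="more progeny"):
        ts_composition_experiment(e_pop, e_phen, de_pop, de_phen, small_genome,
                                  model, rng, designs=[("too big", 10_000, 0)],
                                  n_samples=1)
    out = ts_composition_experiment(
        e_pop, e_phen, de_pop, de_phen, small_genome, model, rng,
        designs=[("Pure E", 240, 0), ("1/3 - DE", 160, 80)],
        n_samples=2, n_val_families=6, val_family_size=25)
    assert set(out.family_class) == {"ExE", "DExE"}
    assert set(out.statistic) == {"accuracy_mean", "variance_accuracy"}
    assert len(out) == 2 * 2 * 2 * 2


def test_mixed_ts_improves_introduction_family_accuracy(bridging_snapshot,
                                                        small_genome):
    """Adding DE progeny to a constant-size TS raises DExE-family accuracy."""
    e_pop, e_phen, de_pop, de_phen, model = bridging_snapshot
    rng = np.random.default_rng(8)
    out = ts_composition_experiment(
        e_pop, e_phen, de_pop, de_phen, small_genome, model, rng,
        designs=[("Pure E", 240, 0), ("1/3 - DE", 160, 80)],
        n_samples=6, n_val_families=10, val_family_size=30)
    acc = out[(out.statistic == "accuracy_mean") & (out.family_class == "DExE")]
    means = acc.groupby("design")["value"].mean()
    assert means["1/3 - DE"] > means["Pure E"]


def test_summarize_shapes():
    df = pd.DataFrame({"scenario": ["a"] * 4 + ["b"] * 4, "year": [1, 1, 2, 2] * 2,
                       "value": np.arange(8.0)})
    out = summarize(df, ["scenario", "year"])
    assert set(out.columns) == {"scenario", "year", "mean", "se", "n"}
    assert (out.n == 2).all()
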