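"""Per-year evaluation metrics and the training-set composition experiment."""

from __future__ import annotations

import numpy as np
import pandas as pd

from bridgesim.genome import GenomeDefinition, expected_heterozygosity
from bridgesim.meiosis import dh_gametes
from bridgesim.population import Population
from bridgesim.prediction import TrainingSet, fit_gblup, predict_gebv
from bridgesim.trait import TraitModel, phenotype, true_breeding_values
from bridgesim.ucpc import CrossPredictor

__all__ = [
    "favorable_allele_frequencies",
    "rare_favorable_mask",
    "compute_metrics",
    "modified_rogers_distance",
    "pcoa",
    "table2_designs",
    "ts_composition_experiment",
    "summarize",
]


def favorable_allele_frequencies(haplotypes: np.ndarray, genome: GenomeDefinition) -> np.ndarray:
    """Per-QTL frequency of the favorable allele in a set of homozygous lines."""
    p1 = np.atleast_2d(haplotypes)[:, genome.qtl_indices].mean(axis=0)
    fav = genome.favorable_allele
    return np.where(fav == 1, p1, 1.0 - p1)


def rare_favorable_mask(haplotypes: np.ndarray, genome: GenomeDefinition,
                        threshold: float = 0.05) -> np.ndarray:
    """QTLs whose favorable allele is rare (p <= threshold) in this population.

    Evaluated once at the end of burn-in and kept fixed per replicate.
    """
    return favorable_allele_frequencies(haplotypes, genome) <= threshold


def _variance_components(tbv: np.ndarray, family: np.ndarray) -> tuple[float, float]:
    """Within- and between-family additive variance of TBVs."""
    fams = np.unique(family)
    means, withins = [], []
    for f in fams:
        v = tbv[family == f]
        means.append(v.mean())
        if v.size > 1:
            withins.append(np.var(v, ddof=1))
    var_within = float(np.mean(withins)) if withins else 0.0
    var_between = float(np.var(means, ddof=1)) if len(means) > 1 else 0.0
    return var_within, var_between


def compute_metrics(pop: Population, genome: GenomeDefinition,
                    rare_mask: np.ndarray) -> dict:
    """Yearly metrics of a breeding cohort.

    mu / mu10 are the mean TBV of the cohort and of its 10 best individuals;
    rare_favorable_freq averages the favorable-allele frequency over the QTLs
    flagged rare at the end of burn-in; he is marker gene diversity.
    """
    tbv = true_breeding_values(pop.haplotypes, genome)
    n10 = min(10, tbv.size)
    mu10 = float(np.sort(tbv)[-n10:].mean())
    fav = favorable_allele_frequencies(pop.haplotypes, genome)
    p_mark = pop.haplotypes[:, genome.marker_indices].mean(axis=0)
    var_w, var_b = _variance_components(tbv, pop.family)
    return {
        "mu": float(tbv.mean()),
        "mu10": mu10,
        "rare_favorable_freq": float(fav[rare_mask].mean()) if rare_mask.any() else float("nan"),
        "he": expected_heterozygosity(p_mark),
        "var_within_family": var_w,
        "var_between_family": var_b,
    }


def modified_rogers_distance(hap_a: np.ndarray, hap_b: np.ndarray | None = None) -> np.ndarray:
    """Pairwise modified Rogers distance between fully homozygous lines.

    For inbreds the squared MRD reduces to the fraction of loci with
    different alleles, so d in [0, 1].
    """
    a = np.atleast_2d(hap_a).astype(np.float64)
    b = a if hap_b is None else np.atleast_2d(hap_b).astype(np.float64)
    L = a.shape[1]
    # mismatch count = a(1-b') + (1-a)b'
    mism = a @ (1.0 - b.T) + (1.0 - a) @ b.T
    return np.sqrt(np.clip(mism / L, 0.0, 1.0))


def pcoa(dist: np.ndarray, n_axes: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a distance matrix (classical scaling).

    Returns (coordinates (n, n_axes), eigenvalues).
    """
    d2 = np.asarray(dist, float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1][:n_axes]
    vals = vals[order]
    coords = vecs[:, order] * np.sqrt(np.clip(vals, 0.0, None))
    return coords, vals


_TABLE2_BASE = [
    # (name, n_E, n_DE) at the reference scale of 3600 E + 1200 DE available
    ("Pure E (3600)", 3600, 0),
    ("Pure DE (1200)", 0, 1200),
    ("1/4 - DE (4800)", 3600, 1200),
    ("Pure E (1200)", 1200, 0),
    ("1/4 - DE (1200)", 900, 300),
    ("1/3 - DE (3600)", 2400, 1200),
    ("1/4 - DE (3600)", 2700, 900),
    ("1/6 - DE (3600)", 3000, 600),
    ("1/12 - DE (3600)", 3300, 300),
    ("1/24 - DE (3600)", 3450, 150),
    ("1/36 - DE (3600)", 3500, 100),
]


def table2_designs(n_e_available: int = 3600, n_de_available: int = 1200) -> list[tuple]:
    """The training-set design grid, scaled to the available pool sizes.

    At the reference scale this reproduces the full grid (pure E, pure DE,
    merged, and the constant-size mixtures down to 1/36 DE); smaller
    snapshots get proportionally scaled counts (at least 1 DE where the
    reference design has any).
    """
    s = n_e_available / 3600.0
    designs = []
    for name, ne, nde in _TABLE2_BASE:
        ne_s = min(int(round(ne * s)), n_e_available)
        nde_s = min(int(round(nde * s)), n_de_available)
        if nde > 0:
            nde_s = max(nde_s, 1)
        designs.append((name, ne_s, nde_s))
    return designs


def _per_family_top(pop: Population, scores: np.ndarray, fraction: float):
    """Indices of the best `fraction` individuals within every family."""
    keep = []
    for f in np.unique(pop.family):
        idx = np.flatnonzero(pop.family == f)
        k = max(1, int(round(fraction * idx.size)))
        keep.extend(idx[np.argsort(scores[idx])[::-1][:k]])
    return np.array(sorted(keep))


def ts_composition_experiment(
    e_pop: Population, e_phen: np.ndarray,
    de_pop: Population, de_phen: np.ndarray,
    genome: GenomeDefinition, trait_model: TraitModel,
    rng: np.random.Generator,
    designs: list[tuple] | None = None,
    n_samples: int = 20,
    n_val_families: int = 50,
    val_family_size: int = 80,
    selected_fraction: float = 0.05,
) -> pd.DataFrame:
    """Effect of training-set size and composition on within-family accuracy.

    From a snapshot of E (breeding) and DE (bridging) progeny of three
    cohorts, a merged-model top-fraction of each family is randomly crossed
    into elite (ExE) and introduction (DExE) validation families.  For every
    design (n_E, n_DE) and random TS draw, a G-BLUP model is fitted and two
    statistics are reported per family class: the mean within-family
    cor(TBV, GEBV) and the variance accuracy cor(sigma, sigma_hat) across
    families (realized family TBV standard deviation vs predicted sigma_c).
    """
    if designs is None:
        designs = table2_designs(e_pop.n, de_pop.n)
    markers = genome.marker_indices

    merged = TrainingSet(
        np.vstack([e_pop.dosages(markers), de_pop.dosages(markers)]),
        np.concatenate([e_phen, de_phen]), composition="E + DE merged")
    model0 = fit_gblup(merged)
    gebv_e = predict_gebv(model0, e_pop.dosages(markers))
    gebv_de = predict_gebv(model0, de_pop.dosages(markers))
    e_par = e_pop.subset(_per_family_top(e_pop, gebv_e, selected_fraction))
    de_par = de_pop.subset(_per_family_top(de_pop, gebv_de, selected_fraction))

    # validation families: random ExE pairs and random DExE pairs
    fams = []  # (class, parent haplotypes, progeny hap, tbv)
    for cls_name, n_fam in (("ExE", n_val_families), ("DExE", n_val_families)):
        for _ in range(n_fam):
            if cls_name == "ExE":
                i1, i2 = rng.choice(e_par.n, size=2, replace=False)
                h1, h2 = e_par.haplotypes[i1], e_par.haplotypes[i2]
            else:
                i1 = rng.integers(de_par.n)
                i2 = rng.integers(e_par.n)
                h1, h2 = de_par.haplotypes[i1], e_par.haplotypes[i2]
            hap = dh_gametes(h1, h2, genome, val_family_size, rng)
            fams.append((cls_name, h1, h2, hap, true_breeding_values(hap, genome)))

    rows = []
    e_dos = e_pop.dosages(markers)
    de_dos = de_pop.dosages(markers)
    for name, n_e, n_de in designs:
        if n_e > e_pop.n or n_de > de_pop.n:
            raise ValueError(f"design {name!r} requests more progeny than available")
        for s in range(n_samples):
            sel_e = rng.choice(e_pop.n, size=n_e, replace=False) if n_e else []
            sel_de = rng.choice(de_pop.n, size=n_de, replace=False) if n_de else []
            dos = np.vstack([m for m, k in ((e_dos[sel_e], n_e), (de_dos[sel_de], n_de)) if k])
            phen = np.concatenate([m for m, k in ((e_phen[sel_e], n_e),
                                                  (de_phen[sel_de], n_de)) if k])
            model = fit_gblup(TrainingSet(dos, phen, composition=name))
            pred = CrossPredictor(genome, model.marker_effects)
            for cls_name in ("ExE", "DExE"):
                accs, sig_true, sig_pred = [], [], []
                for c, h1, h2, hap, tbv in fams:
                    if c != cls_name:
                        continue
                    gebv = predict_gebv(model, 2.0 * hap[:, markers])
                    if np.std(tbv) > 0 and np.std(gebv) > 0:
                        accs.append(np.corrcoef(tbv, gebv)[0, 1])
                    sig_true.append(np.std(tbv, ddof=1))
                    out = pred.evaluate(h1[None, markers], h2[None, markers],
                                        np.zeros(1), np.zeros(1), i=0.0)
                    sig_pred.append(out["sigma"][0])
                rows.append((name, s, cls_name, "accuracy_mean", float(np.mean(accs))))
                if np.std(sig_true) > 0 and np.std(sig_pred) > 0:
                    var_acc = float(np.corrcoef(sig_true, sig_pred)[0, 1])
                else:
                    var_acc = float("nan")
                rows.append((name, s, cls_name, "variance_accuracy", var_acc))
    return pd.DataFrame(rows, columns=["design", "sample", "family_class",
                                       "statistic", "value"])


def summarize(result: pd.DataFrame, by: list[str], value: str = "value") -> pd.DataFrame:
    """Mean +/- standard error tables over replicates/samples."""
    g = result.groupby(by)[value]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"sem": "se", "count": "n"})
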