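"""G-BLUP genomic prediction with marker-effect back-solving.

The mixed model is y = 1 mu + g + e with g ~ N(0, sigma2_g G) and the
VanRaden genomic relationship G = Zc Zc' / s, where Zc are marker dosages
centered with training-set allele frequencies and s = sum_k 2 p_k (1 - p_k).
Variance components are estimated by REML on the single variance ratio via
the spectral decomposition of G (obtained from the SVD of Zc, which carries
the same eigenstructure).  Marker effects are recovered by back-solving
a_hat = Zc' G^+ u_hat / s, so GEBVs extend to any genotyped individual,
including donors never phenotyped in the program.  G-BLUP here is exactly
equivalent to ridge regression (RR-BLUP) on centered markers with shrinkage
lambda = sigma2_e / (sigma2_g / s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import pearsonr

from bridgesim.genome import GenomeDefinition
from bridgesim.population import Population
from bridgesim.trait import true_breeding_values

__all__ = [
    "TrainingSet",
    "PredictionModel",
    "fit_gblup",
    "predict_gebv",
    "within_family_accuracy",
    "DegenerateTrainingSet",
]


class DegenerateTrainingSet(ValueError):
    """Raised when the training system is singular (e.g. no marker variation)."""


@dataclass
class TrainingSet:
    """Genotyped and phenotyped individuals used to fit the model.

    ``genotypes`` holds marker dosages (n, n_markers) in {0, 2}; ``meta``
    carries per-individual cohort metadata (year, program, family).
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    meta: pd.DataFrame | None = None
    composition: str = ""

    def __post_init__(self):
        if self.genotypes.shape[0] != np.asarray(self.phenotypes).size:
            raise ValueError("one phenotype per individual is required")

    @classmethod
    def from_population(cls, pop: Population, phenotypes: np.ndarray,
                        genome: GenomeDefinition, composition: str = "") -> "TrainingSet":
        meta = pd.DataFrame({"id": pop.ids, "family": pop.family,
                             "year": pop.year, "program": pop.program})
        return cls(pop.dosages(genome.marker_indices), np.asarray(phenotypes, float),
                   meta, composition)


@dataclass
class PredictionModel:
    """Fitted G-BLUP state: intercept, training GEBVs, back-solved effects."""

    intercept: float
    marker_effects: np.ndarray      # per allele copy of allele 1
    allele_freq: np.ndarray         # training-set frequencies used for centering
    gebv_train: np.ndarray
    var_genetic: float
    var_residual: float
    converged: bool = True
    info: dict = field(default_factory=dict)

    @property
    def variance_ratio(self) -> float:
        return self.var_residual / max(self.var_genetic, 1e-300)

    def to_table(self) -> pd.DataFrame:
        """Model dump: per-marker back-solved effect and centering frequency."""
        return pd.DataFrame({
            "marker": [f"M{k + 1}" for k in range(self.marker_effects.size)],
            "effect": self.marker_effects,
            "allele_freq": self.allele_freq,
        })


def _reml_neg2ll(log_gamma: float, d2: np.ndarray, c2: np.ndarray,
                 rss_out: float, n: int) -> float:
    # gamma = sigma2_a / sigma2_e (marker-variance scale); profile sigma2_e out
    gamma = np.exp(log_gamma)
    v = gamma * d2 + 1.0
    s2e = (np.sum(c2 / v) + rss_out) / (n - 1)
    return (n - 1) * np.log(max(s2e, 1e-300)) + float(np.sum(np.log(v)))


def fit_gblup(ts: TrainingSet, fallback_ratio: float | None = None) -> PredictionModel:
    """Fit the G-BLUP model by REML and back-solve marker effects.

    ``fallback_ratio`` (sigma2_e / sigma2_g) is used if the REML surface is
    degenerate (e.g. no detectable genetic variance); its use is recorded in
    ``model.info`` and warned about.
    """
    y = np.asarray(ts.phenotypes, dtype=float)
    n = y.size
    if n < 2:
        raise DegenerateTrainingSet("need at least 2 training individuals")
    dos = np.asarray(ts.genotypes, dtype=float)
    p = dos.mean(axis=0) / 2.0
    s = float(np.sum(2.0 * p * (1.0 - p)))
    if s <= 0:
        raise DegenerateTrainingSet("all training genotypes are identical")
    zc = dos - 2.0 * p  # exactly column-centered

    mu = float(y.mean())
    yt = y - mu
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        L = dos.shape[1]
        return PredictionModel(mu, np.zeros(L), p, np.zeros(n), 0.0, 0.0,
                               info={"degenerate": "constant phenotypes"})

    u_svd, d, vt = np.linalg.svd(zc, full_matrices=False)
    keep = d > d.max() * 1e-10
    u_svd, d, vt = u_svd[:, keep], d[keep], vt[keep]
    c = u_svd.T @ yt
    c2 = c ** 2
    rss_out = max(float(yt @ yt - c2.sum()), 0.0)
    d2 = d ** 2

    res = minimize_scalar(_reml_neg2ll, bounds=(-25.0, 25.0), method="bounded",
                          args=(d2, c2, rss_out, n))
    converged = bool(res.success)
    info: dict = {"composition": ts.composition, "reml_neg2ll": float(res.fun)}
    if converged:
        gamma = float(np.exp(res.x))
    elif fallback_ratio is not None:
        # fallback_ratio is sigma2_e / sigma2_g; gamma is on the marker scale
        gamma = 1.0 / (fallback_ratio * s)
        info["fallback_ratio_used"] = fallback_ratio
        warnings.warn("REML did not converge; using fallback variance ratio")
    else:
        raise DegenerateTrainingSet("REML did not converge and no fallback given")

    v = gamma * d2 + 1.0
    s2e = float((np.sum(c2 / v) + rss_out) / (n - 1))
    s2a = gamma * s2e                    # per-marker effect variance
    s2g = s2a * s                        # genetic variance on the G scale
    lam = s2e / max(s2a, 1e-300)         # ridge shrinkage

    # a_hat = (Zc'Zc + lam I)^-1 Zc' yt == Zc' G^+ u_hat / s  (same SVD route)
    a_hat = vt.T @ ((d / (d2 + lam)) * c)
    gebv = zc @ a_hat

    return PredictionModel(mu, a_hat, p, gebv, s2g, s2e, converged or
                           fallback_ratio is not None, info)


def predict_gebv(model: PredictionModel, genotypes: np.ndarray) -> np.ndarray:
    """GEBV = intercept + (dosage - 2 p_bar)' a_hat, with TS centering.

    Applicable to any genotyped individual on the same marker set.
    """
    dos = np.atleast_2d(np.asarray(genotypes, dtype=float))
    if dos.shape[1] != model.marker_effects.size:
        raise ValueError(
            f"marker set mismatch: model has {model.marker_effects.size} markers, "
            f"genotypes have {dos.shape[1]}"
        )
    return model.intercept + (dos - 2.0 * model.allele_freq) @ model.marker_effects


def within_family_accuracy(model: PredictionModel, family: Population,
                           genome: GenomeDefinition) -> float:
    """Pearson correlation of TBV and GEBV within one family.

    Returns NaN (with a warning) when either variable is constant within the
    family, where the correlation is undefined.
    """
    tbv = true_breeding_values(family.haplotypes, genome)
    gebv = predict_gebv(model, family.dosages(genome.marker_indices))
    if np.std(tbv) == 0 or np.std(gebv) == 0:
        warnings.warn("within-family accuracy undefined: constant TBV or GEBV")
        return float("nan")
    return float(pearsonr(tbv, gebv)[0])
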