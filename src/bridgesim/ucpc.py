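"""Usefulness criterion with parental contributions (UCPC) for DH crosses.

For a biparental cross of homozygous parents producing DH progeny, write
s_j = (dosage1_j - dosage2_j) / 2 in {-1, 0, 1} and c_jk for the pairwise
recombination fraction (0.5 across chromosomes).  With per-allele effects
a_j, the progeny value has

    mean      mu_c     = (GEBV1 + GEBV2) / 2
    variance  sigma2_c = sum_jk a_j a_k s_j s_k (1 - 2 c_jk)

and the usefulness criterion of the cross is UC = mu_c + i * h * sigma_c,
the expected mean of the fraction p of progeny retained by truncation on
predicted value (i the standardized selection intensity, h the selection
accuracy).  Under the same normal approximation the selected fraction is
genetically closer to the better parent: the expected contribution of parent
1 is 1/2 + i*h*cov(contribution, value)/sigma_c and the expected allele
frequency at locus l is the parental mean frequency plus
i*h/(2 sigma_c) * s_l * sum_k a_k s_k (1 - 2 c_lk), both clamped to [0, 1].
Because 1 - 2c = exp(-2 d / 100) under Haldane, the (1 - 2c) kernel is block
diagonal over chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from bridgesim.genome import GenomeDefinition

__all__ = [
    "selection_intensity",
    "DiversityTrajectory",
    "he_constraint",
    "CrossPredictor",
    "CrossPrediction",
    "predict_cross_mean",
    "predict_cross_variance",
    "selected_fraction_profile",
    "expected_diversity",
]


def selection_intensity(p_selected: float) -> float:
    """Standardized intensity i = phi(z) / p for upper-tail fraction p."""
    if not 0 < p_selected <= 1:
        raise ValueError("selected fraction must be in (0, 1]")
    if p_selected == 1:
        return 0.0
    z = norm.isf(p_selected)
    return float(norm.pdf(z) / p_selected)


@dataclass(frozen=True)
class DiversityTrajectory:
    """Linear-then-constant genome-wide diversity floor He(t).

    He(0) = he0 (diversity at the end of burn-in), declining (or constant)
    linearly to he_star at the horizon t_star, constant afterwards.
    """

    he0: float
    he_star: float
    t_star: int

    def at(self, t: float) -> float:
        if t >= self.t_star:
            return self.he_star
        return self.he0 + (t / self.t_star) * (self.he_star - self.he0)

    @classmethod
    def constant(cls, he0: float) -> "DiversityTrajectory":
        return cls(he0, he0, 1)


def he_constraint(t: float, trajectory: DiversityTrajectory) -> float:
    """Diversity floor He(t) for the cross-selection constraint at year t."""
    return trajectory.at(t)


class CrossPredictor:
    """Batched UCPC evaluation of candidate crosses on a fixed effect set.

    Parameters
    ----------
    genome : map provider for the (1 - 2c) linkage kernel.
    effects : per-allele effects aligned with ``loci`` (back-solved marker
        effects in the breeding scenarios, or true QTL effects for oracles).
    loci : locus indices the effects refer to; defaults to the markers.
    """

    def __init__(self, genome: GenomeDefinition, effects: np.ndarray,
                 loci: np.ndarray | None = None, dtype=np.float32):
        self.genome = genome
        self.loci = genome.marker_indices if loci is None else np.asarray(loci)
        self.effects = np.asarray(effects, dtype=float)
        if self.effects.size != self.loci.size:
            raise ValueError("effects length must match locus set")
        chrom = genome.chromosome[self.loci]
        pos = genome.position_cm[self.loci]
        self._blocks = []
        for c in np.unique(chrom):
            idx = np.where(chrom == c)[0]
            d = np.abs(pos[idx][:, None] - pos[idx][None, :])
            # = 1 - 2c; float32 (default) keeps large candidate batches cheap,
            # float64 serves the exact single-cross paths
            self._blocks.append((idx, np.exp(-2.0 * d / 100.0).astype(dtype)))
        self._eff32 = self.effects.astype(dtype)

    def _kernel_matvec(self, w: np.ndarray) -> np.ndarray:
        """u = w @ B with B the block-diagonal (1 - 2c) kernel."""
        u = np.empty_like(w)
        for idx, b in self._blocks:
            u[:, idx] = w[:, idx] @ b
        return u

    def evaluate(self, hap1: np.ndarray, hap2: np.ndarray,
                 gebv1: np.ndarray, gebv2: np.ndarray,
                 i: float, h: float = 1.0) -> dict:
        """UCPC predictions for a batch of crosses.

        ``hap1``/``hap2`` are (n_pairs, L) parental haplotypes restricted to
        ``self.loci``; returns mu, sigma, uc, contribution of parent 1, and
        the (n_pairs, L) expected selected-fraction allele frequencies.
        """
        hap1 = np.atleast_2d(hap1)
        hap2 = np.atleast_2d(hap2)
        delta = hap1.astype(np.int8) - hap2.astype(np.int8)  # s_j in {-1,0,1}
        w = delta * self._eff32
        u = self._kernel_matvec(w)
        sigma2 = np.einsum("ij,ij->i", w, u, dtype=np.float64)
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        mu = 0.5 * (np.asarray(gebv1, float) + np.asarray(gebv2, float))
        uc = mu + i * h * sigma

        with np.errstate(divide="ignore", invalid="ignore"):
            coef = np.where(sigma > 0, i * h / (2.0 * sigma), 0.0)
        contrib1 = np.clip(0.5 + coef * u.mean(axis=1, dtype=np.float64), 0.0, 1.0)
        freqs = delta * u                        # reuse the (n, L) buffer
        freqs *= coef[:, None].astype(np.float32)
        freqs += 0.5 * (hap1 + hap2).astype(np.float32)
        np.clip(freqs, 0.0, 1.0, out=freqs)
        return {"mu": mu, "sigma": sigma, "uc": uc,
                "contribution1": contrib1, "selected_freqs": freqs}


@dataclass
class CrossPrediction:
    """UCPC profile of a single cross (see ``selected_fraction_profile``)."""

    mu: float
    sigma: float
    intensity: float
    accuracy: float
    uc: float
    contributions: tuple
    selected_freqs: np.ndarray


def predict_cross_mean(gebv1: float, gebv2: float) -> float:
    """Expected DH progeny mean: the parental GEBV average."""
    return 0.5 * (gebv1 + gebv2)


def predict_cross_variance(parent1_hap: np.ndarray, parent2_hap: np.ndarray,
                           effects: np.ndarray, genome: GenomeDefinition,
                           loci: np.ndarray | None = None) -> float:
    """DH progeny variance including linkage (co)variances for one cross."""
    pred = CrossPredictor(genome, effects, loci, dtype=np.float64)
    sel = pred.loci
    out = pred.evaluate(parent1_hap[None, sel], parent2_hap[None, sel],
                        np.zeros(1), np.zeros(1), i=0.0)
    return float(out["sigma"][0] ** 2)


def selected_fraction_profile(parent1_hap: np.ndarray, parent2_hap: np.ndarray,
                              gebv1: float, gebv2: float, i: float,
                              predictor: CrossPredictor, h: float = 1.0) -> CrossPrediction:
    """Full UCPC profile of one cross at intensity i and accuracy h.

    With i = 0 (or a monomorphic cross) contributions are (1/2, 1/2) and
    UC = mu_c.
    """
    sel = predictor.loci
    out = predictor.evaluate(parent1_hap[None, sel], parent2_hap[None, sel],
                             np.asarray([gebv1]), np.asarray([gebv2]), i, h)
    c1 = float(out["contribution1"][0])
    return CrossPrediction(
        mu=float(out["mu"][0]), sigma=float(out["sigma"][0]), intensity=i,
        accuracy=h, uc=float(out["uc"][0]), contributions=(c1, 1.0 - c1),
        selected_freqs=out["selected_freqs"][0],
    )


def expected_diversity(selected_freqs: np.ndarray) -> float:
    """Expected He of the pooled selected fractions of a cross set.

    ``selected_freqs`` is (n_crosses, L); families are pooled with equal
    weights, D = mean_l 2 p_bar_l (1 - p_bar_l).
    """
    p = np.atleast_2d(selected_freqs).mean(axis=0)
    return float(np.mean(2.0 * p * (1.0 - p)))
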