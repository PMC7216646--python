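"""True breeding values and phenotype simulation.

The trait is fully additive over QTLs.  Phenotypes are line means over
``n_env`` environments with plot error variance calibrated once, on the
founder panel, to a target single-plot repeatability r:
sigma2_E = sigma2_G0 * (1 - r) / r, where sigma2_G0 is the TBV variance among
founders.  There is no genotype-by-environment interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bridgesim.genome import GenomeDefinition

__all__ = [
    "TraitModel",
    "true_breeding_values",
    "calibrate_error_variance",
    "phenotype",
    "simulate_plots",
    "estimate_repeatability",
]


def true_breeding_values(haplotypes: np.ndarray, genome: GenomeDefinition) -> np.ndarray:
    """TBV = sum_j beta_j * dosage_j over the QTLs (dosage in {0, 2})."""
    hap = np.atleast_2d(haplotypes)
    dos = 2.0 * hap[:, genome.qtl_indices]
    tbv = dos @ genome.qtl_effects
    return tbv if haplotypes.ndim > 1 else float(tbv[0])


def calibrate_error_variance(founder_haplotypes: np.ndarray, genome: GenomeDefinition,
                             repeatability_target: float = 0.4) -> float:
    """Plot error variance giving the target repeatability in the founders."""
    r = repeatability_target
    if not 0 < r < 1:
        raise ValueError("repeatability target must be in (0, 1)")
    tbv = true_breeding_values(founder_haplotypes, genome)
    var_g0 = float(np.var(tbv, ddof=1))
    if var_g0 <= 0:
        raise ValueError("founder population has zero genetic variance")
    return var_g0 * (1.0 - r) / r


@dataclass(frozen=True)
class TraitModel:
    """Trait architecture reference plus the fixed phenotyping design."""

    genome: GenomeDefinition
    plot_error_variance: float
    n_env: int = 4
    repeatability_target: float = 0.4

    def __post_init__(self):
        if self.plot_error_variance < 0:
            raise ValueError("plot error variance must be >= 0")
        if self.n_env < 1:
            raise ValueError("n_env must be >= 1")

    @classmethod
    def calibrated(cls, founder_haplotypes: np.ndarray, genome: GenomeDefinition,
                   repeatability_target: float = 0.4, n_env: int = 4) -> "TraitModel":
        s2e = calibrate_error_variance(founder_haplotypes, genome, repeatability_target)
        return cls(genome, s2e, n_env, repeatability_target)


def phenotype(haplotypes: np.ndarray, model: TraitModel,
              rng: np.random.Generator) -> np.ndarray:
    """Line-mean phenotypes: y = TBV + mean of n_env plot errors."""
    hap = np.atleast_2d(haplotypes)
    tbv = true_breeding_values(hap, model.genome)
    sd = np.sqrt(model.plot_error_variance / model.n_env)
    return tbv + rng.normal(0.0, sd, size=hap.shape[0])


def simulate_plots(haplotypes: np.ndarray, model: TraitModel,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_lines, n_env) single-plot phenotypes for repeatability diagnostics."""
    tbv = true_breeding_values(haplotypes, model.genome)
    noise = rng.normal(0.0, np.sqrt(model.plot_error_variance),
                       size=(tbv.size, model.n_env))
    return tbv[:, None] + noise


def estimate_repeatability(plots: np.ndarray) -> float:
    """Realized single-plot repeatability from a lines x plots table.

    Uses the one-way ANOVA estimator: r = s2_g / (s2_g + MSW) with
    s2_g = (MSB - MSW) / k, i.e. the intraclass correlation of plots within
    lines.
    """
    n, k = plots.shape
    line_means = plots.mean(axis=1)
    msw = float(((plots - line_means[:, None]) ** 2).sum() / (n * (k - 1)))
    msb = float(k * np.var(line_means, ddof=1))
    s2g = max((msb - msw) / k, 0.0)
    return s2g / (s2g + msw)
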