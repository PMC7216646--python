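"""Meiosis and doubled-haploid family production.

Crossovers follow a homogeneous Poisson process on the genetic map (no
interference), which is the process underlying Haldane's mapping function.
For loci ordered along a chromosome this makes the transmitted phase a Markov
chain: between adjacent loci at distance d cM the phase switches with
probability c = (1 - exp(-2 d / 100)) / 2, independently across intervals.
Gametes of the virtual F1 between two homozygous parents are simulated this
way and then doubled, so every DH progeny is fully homozygous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bridgesim.genome import GenomeDefinition
from bridgesim.population import Population

__all__ = ["recombination_fraction", "dh_gametes", "make_dh_family", "CrossSpec"]


def recombination_fraction(d_cm):
    """Haldane inverse: map distance (cM) -> recombination fraction in [0, 0.5).

    Vectorized; raises ``ValueError`` for negative distances.  Loci on
    different chromosomes have c = 0.5 (handled by callers).
    """
    d = np.asarray(d_cm, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be non-negative")
    c = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return c if c.ndim else float(c)


@dataclass(frozen=True)
class CrossSpec:
    """A biparental cross: two distinct homozygous parents and a family size."""

    parent1_id: int
    parent2_id: int
    n_progeny: int

    def __post_init__(self):
        if self.parent1_id == self.parent2_id:
            raise ValueError("self-cross: parent ids must differ")
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")


def _phase_matrix(genome: GenomeDefinition, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, L) matrix of transmitted-parent indicators (0 = parent 1)."""
    L = genome.n_loci
    phase = np.empty((n, L), dtype=np.uint8)
    for c in np.unique(genome.chromosome):
        idx = np.where(genome.chromosome == c)[0]
        d = np.diff(genome.position_cm[idx])
        switch_p = recombination_fraction(d)
        start = rng.integers(0, 2, size=(n, 1), dtype=np.uint8)
        if idx.size > 1:
            switches = (rng.random((n, idx.size - 1)) < switch_p).astype(np.uint8)
            phase[:, idx] = (start + np.concatenate(
                [np.zeros((n, 1), dtype=np.uint8), np.cumsum(switches, axis=1, dtype=np.uint32)],
                axis=1, dtype=np.uint32, casting="unsafe")) % 2
        else:
            phase[:, idx] = start
    return phase


def dh_gametes(parent1_hap: np.ndarray, parent2_hap: np.ndarray,
               genome: GenomeDefinition, n: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate n gametes of the F1 of two homozygous parents, then double.

    Returns an (n, L) haplotype matrix in {0, 1}; each row defines one fully
    homozygous DH line.
    """
    phase = _phase_matrix(genome, n, rng)
    p1 = np.asarray(parent1_hap, dtype=np.uint8)
    p2 = np.asarray(parent2_hap, dtype=np.uint8)
    return np.where(phase == 0, p1[None, :], p2[None, :]).astype(np.uint8)


def make_dh_family(cross: CrossSpec, parents: Population, genome: GenomeDefinition,
                   rng: np.random.Generator, family_id: int = 0, year: int = 0,
                   program: str = "E", id_start: int = 0) -> Population:
    """Produce a DH family from a cross between two parents of ``parents``.

    Parent ids are looked up in ``parents.ids``; both must exist and be fully
    homozygous (guaranteed for DH material).
    """
    where1 = np.flatnonzero(parents.ids == cross.parent1_id)
    where2 = np.flatnonzero(parents.ids == cross.parent2_id)
    if where1.size != 1 or where2.size != 1:
        raise KeyError("cross parents not found (or ambiguous) in population")
    hap = dh_gametes(parents.haplotypes[where1[0]], parents.haplotypes[where2[0]],
                     genome, cross.n_progeny, rng)
    ids = np.arange(id_start, id_start + cross.n_progeny)
    return Population.from_haplotypes(hap, ids=ids, family=family_id, year=year,
                                      program=program)
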