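"""Container for cohorts of fully homozygous DH lines."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Population"]


@dataclass
class Population:
    """A set of fully homozygous individuals with cohort bookkeeping.

    ``haplotypes`` is (n, L) in {0, 1}; one haplotype fully defines the
    diploid genotype of a DH line.  ``family`` groups full sibs, ``year`` is
    the cohort year, and ``program`` labels the program of origin per
    individual: founders/donors "D", bridging progeny "DE", elites "E".
    """

    haplotypes: np.ndarray
    ids: np.ndarray
    family: np.ndarray
    year: np.ndarray
    program: np.ndarray

    @classmethod
    def from_haplotypes(cls, hap: np.ndarray, ids=None, family=0, year=0,
                        program="E") -> "Population":
        n = hap.shape[0]
        ids = np.arange(n) if ids is None else np.asarray(ids)
        return cls(
            haplotypes=np.asarray(hap, dtype=np.uint8),
            ids=ids,
            family=np.broadcast_to(np.asarray(family), (n,)).copy(),
            year=np.broadcast_to(np.asarray(year), (n,)).copy(),
            program=np.broadcast_to(np.asarray(program, dtype=object), (n,)).copy(),
        )

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        hap = self.haplotypes if loci is None else self.haplotypes[:, loci]
        return 2 * hap.astype(np.int16)

    def subset(self, idx) -> "Population":
        return Population(self.haplotypes[idx], self.ids[idx], self.family[idx],
                          self.year[idx], self.program[idx])

    @staticmethod
    def concat(pops: list["Population"]) -> "Population":
        return Population(
            np.vstack([p.haplotypes for p in pops]),
            np.concatenate([p.ids for p in pops]),
            np.concatenate([p.family for p in pops]),
            np.concatenate([p.year for p in pops]),
            np.concatenate([p.program for p in pops]),
        )

    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.haplotypes,
                          columns=[f"L{i + 1}" for i in range(self.haplotypes.shape[1])])
        df.insert(0, "program", self.program)
        df.insert(0, "year", self.year)
        df.insert(0, "family", self.family)
        df.insert(0, "id", self.ids)
        return df

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "Population":
        meta = ["id", "family", "year", "program"]
        hap = df.drop(columns=meta).to_numpy().astype(np.uint8)
        return cls(hap, df["id"].to_numpy(), df["family"].to_numpy(),
                   df["year"].to_numpy(), df["program"].to_numpy(dtype=object))
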