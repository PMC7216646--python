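"""Genome architecture and synthetic founder panels.

The trait is purely additive: 1000 biallelic QTLs with Gaussian effects
(variance 0.05 trait-units^2) placed on a genetic map with a minimum spacing
of 0.2 cM between QTLs on the same chromosome, plus 2000 non-causal SNPs used
as genotyping markers.  Founders are fully homozygous inbred lines structured
into subgroups; the synthetic panel generator emulates a structured maize dent
panel (82 + 57 + 199 lines) by drawing ancestral allele frequencies from a
symmetric Beta distribution and letting each subgroup drift away from them
(Balding-Nichols divergence), calibrated so that realized marker
heterozygosity matches configurable targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MapConfig",
    "GenomeDefinition",
    "FounderPanel",
    "GenomeError",
    "CalibrationError",
    "sample_genome",
    "synthesize_founders",
    "load_founders",
    "save_founders",
    "write_map",
    "expected_heterozygosity",
]

MIN_QTL_SPACING_CM = 0.2


class GenomeError(ValueError):
    """Raised when a genetic map cannot host the requested architecture."""


class CalibrationError(RuntimeError):
    """Raised when founder diversity targets cannot be reached."""


@dataclass(frozen=True)
class MapConfig:
    """Genetic map layout and locus budget.

    Defaults are maize-like: 10 chromosomes of 160 cM with candidate loci on a
    uniform 0.1 cM grid, hosting 1000 QTLs and 2000 neutral markers.
    """

    n_chromosomes: int = 10
    chromosome_length_cm: float = 160.0
    candidate_spacing_cm: float = 0.1
    n_qtl: int = 1000
    n_markers: int = 2000


@dataclass(frozen=True)
class GenomeDefinition:
    """Immutable description of loci, map positions and trait architecture.

    Loci are stored sorted by (chromosome, position).  ``qtl_effects[j]`` is
    the signed additive effect of allele 1 at QTL ``qtl_indices[j]`` per allele
    copy; the favorable allele is 1 when the effect is positive, else 0.
    """

    chromosome: np.ndarray          # (L,) int, 1-based chromosome id
    position_cm: np.ndarray         # (L,) float, position within chromosome
    qtl_indices: np.ndarray         # (n_qtl,) int indices into loci
    marker_indices: np.ndarray      # (n_markers,) int indices into loci
    qtl_effects: np.ndarray         # (n_qtl,) signed effect of allele 1

    @property
    def n_loci(self) -> int:
        return self.chromosome.size

    @property
    def n_chromosomes(self) -> int:
        return int(self.chromosome.max())

    @property
    def favorable_allele(self) -> np.ndarray:
        """Per-QTL allele (0/1) whose dosage increase raises the trait."""
        return (self.qtl_effects > 0).astype(np.int8)

    def effects_by_locus(self) -> np.ndarray:
        """Signed allele-1 effect for every locus (0 at non-QTL loci)."""
        out = np.zeros(self.n_loci)
        out[self.qtl_indices] = self.qtl_effects
        return out

    def validate(self) -> None:
        if np.intersect1d(self.qtl_indices, self.marker_indices).size:
            raise GenomeError("QTL and marker index sets overlap")
        if (self.position_cm < 0).any():
            raise GenomeError("negative map positions")
        for c in np.unique(self.chromosome):
            pos = self.position_cm[self.chromosome == c]
            if (np.diff(pos) < 0).any():
                raise GenomeError("positions not sorted within chromosome")
        qc = self.chromosome[self.qtl_indices]
        qp = self.position_cm[self.qtl_indices]
        for c in np.unique(qc):
            gaps = np.diff(np.sort(qp[qc == c]))
            if gaps.size and gaps.min() < MIN_QTL_SPACING_CM - 1e-9:
                raise GenomeError("QTL spacing below minimum")


def _allocate_counts(rng: np.random.Generator, weights: np.ndarray,
                     total: int, capacity: np.ndarray) -> np.ndarray:
    """Multinomial allocation of loci to chromosomes respecting capacities."""
    counts = rng.multinomial(total, weights / weights.sum())
    # move any excess over capacity to chromosomes with slack
    for _ in range(1000):
        excess = counts - capacity
        if (excess <= 0).all():
            return counts
        over = np.where(excess > 0)[0]
        under = np.where(counts < capacity)[0]
        if under.size == 0:
            break
        for i in over:
            move = excess[i]
            counts[i] -= move
            slack = capacity[under] - counts[under]
            take = np.minimum(slack, move)
            # spread over chromosomes with slack, largest slack first
            order = np.argsort(-slack)
            left = move
            for j in order:
                t = min(left, slack[j])
                counts[under[j]] += t
                left -= t
                if left == 0:
                    break
    raise GenomeError("cannot allocate loci within chromosome capacities")


def sample_genome(map_config: MapConfig = MapConfig(), rng_seed: int = 0) -> GenomeDefinition:
    """Sample QTL/marker positions and QTL effects for a new genome.

    QTLs keep a minimum pairwise spacing of 0.2 cM on the same chromosome and
    receive i.i.d. Normal(0, 0.05) additive effects; the favorable allele
    follows the sign of the effect, which is symmetric around zero.  Markers
    are drawn from the remaining candidate grid positions.

    Raises
    ------
    GenomeError
        If the map cannot host the requested number of QTLs at the minimum
        spacing, or not enough candidate positions remain for the markers.
    """
    cfg = map_config
    rng = np.random.default_rng(rng_seed)
    n_chrom = cfg.n_chromosomes
    length = float(cfg.chromosome_length_cm)
    spacing = float(cfg.candidate_spacing_cm)

    grid = np.arange(0.0, length + 1e-9, spacing)
    n_grid = grid.size
    # min index gap between QTLs on the candidate grid
    m = int(np.ceil(MIN_QTL_SPACING_CM / spacing - 1e-12))
    cap_per_chrom = (n_grid - 1) // m + 1
    capacity = np.full(n_chrom, cap_per_chrom)
    if capacity.sum() < cfg.n_qtl:
        raise GenomeError(
            f"map cannot host {cfg.n_qtl} QTLs at {MIN_QTL_SPACING_CM} cM spacing "
            f"(capacity {int(capacity.sum())})"
        )
    if n_chrom * n_grid < cfg.n_qtl + cfg.n_markers:
        raise GenomeError("not enough candidate positions for QTLs + markers")

    weights = np.full(n_chrom, length)
    qtl_counts = _allocate_counts(rng, weights, cfg.n_qtl, capacity)

    chrom_col, pos_col, is_qtl = [], [], []
    for c in range(n_chrom):
        k = int(qtl_counts[c])
        # uniform sample of k grid indices with pairwise gap >= m
        # (bijection with unconstrained sorted sampling)
        if k > 0:
            reduced = rng.choice(n_grid - (k - 1) * (m - 1), size=k, replace=False)
            reduced.sort()
            qtl_idx = reduced + (m - 1) * np.arange(k)
        else:
            qtl_idx = np.array([], dtype=int)
        free = np.setdiff1d(np.arange(n_grid), qtl_idx, assume_unique=True)
        chrom_col.append((c + 1, qtl_idx, free))

    # markers: uniform over all free grid positions genome-wide
    free_sizes = np.array([f.size for _, _, f in chrom_col])
    total_free = int(free_sizes.sum())
    if total_free < cfg.n_markers:
        raise GenomeError("not enough free candidate positions for markers")
    flat_pick = rng.choice(total_free, size=cfg.n_markers, replace=False)
    flat_pick.sort()
    offsets = np.concatenate([[0], np.cumsum(free_sizes)])

    recs = []  # (chrom, pos, class)
    for ci, (c, qtl_idx, free) in enumerate(chrom_col):
        for g in qtl_idx:
            recs.append((c, grid[g], True))
        local = flat_pick[(flat_pick >= offsets[ci]) & (flat_pick < offsets[ci + 1])] - offsets[ci]
        for g in free[local]:
            recs.append((c, grid[g], False))
    recs.sort(key=lambda r: (r[0], r[1]))
    chrom = np.array([r[0] for r in recs], dtype=np.int16)
    pos = np.array([r[1] for r in recs])
    qmask = np.array([r[2] for r in recs])
    qtl_indices = np.where(qmask)[0]
    marker_indices = np.where(~qmask)[0]
    effects = rng.normal(0.0, np.sqrt(0.05), size=cfg.n_qtl)

    genome = GenomeDefinition(chrom, pos, qtl_indices, marker_indices, effects)
    genome.validate()
    return genome


def expected_heterozygosity(freqs: np.ndarray) -> float:
    """Gene diversity He = mean over loci of 2 p (1 - p)."""
    p = np.asarray(freqs, dtype=float)
    return float(np.mean(2.0 * p * (1.0 - p)))


@dataclass
class FounderPanel:
    """A panel of fully homozygous lines: one haplotype per line.

    ``haplotypes`` is (n_lines, n_loci) with alleles in {0, 1}; the diploid
    dosage of allele 1 is twice the haplotype.  ``group_labels`` assigns each
    line to a subgroup (0-based).
    """

    haplotypes: np.ndarray
    group_labels: np.ndarray
    achieved_he: dict = field(default_factory=dict)

    @property
    def panel_size(self) -> int:
        return self.haplotypes.shape[0]

    def dosages(self) -> np.ndarray:
        return 2 * self.haplotypes.astype(np.int16)

    def marker_he(self, genome: GenomeDefinition, loci: str = "markers") -> float:
        idx = genome.marker_indices if loci == "markers" else genome.qtl_indices
        p = self.haplotypes[:, idx].mean(axis=0)
        return expected_heterozygosity(p)

    def subgroup(self, g: int) -> "FounderPanel":
        keep = self.group_labels == g
        return FounderPanel(self.haplotypes[keep], self.group_labels[keep])

    def validate(self, genome: GenomeDefinition | None = None) -> None:
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("founder alleles must be 0/1 (homozygous lines)")
        if genome is not None and self.haplotypes.shape[1] != genome.n_loci:
            raise ValueError("panel locus count does not match genome")


def _draw_panel(rng: np.random.Generator, n_loci: int, group_sizes: tuple,
                theta: float, drift: np.ndarray) -> FounderPanel:
    p_anc = np.clip(rng.beta(theta, theta, size=n_loci), 1e-6, 1 - 1e-6)
    haps, labels = [], []
    for g, (size, f) in enumerate(zip(group_sizes, drift)):
        if f <= 1e-9:
            p_g = p_anc
        else:
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            p_g = rng.beta(a, b)
        haps.append((rng.random((size, n_loci)) < p_g).astype(np.uint8))
        labels.append(np.full(size, g))
    return FounderPanel(np.vstack(haps), np.concatenate(labels))


def synthesize_founders(
    genome: GenomeDefinition,
    group_spec: tuple = (82, 57, 199),
    diversity_targets: tuple = (0.28, 0.13),
    rng_seed: int = 0,
    target_group: int = 1,
    drift_other: float = 0.15,
    rel_tol: float = 0.15,
    max_iter: int = 15,
) -> FounderPanel:
    """Generate a structured panel of homozygous lines with calibrated diversity.

    Ancestral allele frequencies are Beta(theta, theta); each subgroup drifts
    from them with a Balding-Nichols divergence parameter.  ``theta`` and the
    drift of ``target_group`` are calibrated iteratively so the full-panel
    marker He matches ``diversity_targets[0]`` and the target subgroup's He
    matches ``diversity_targets[1]`` (both within ``rel_tol`` relative).

    Raises
    ------
    CalibrationError
        If the targets are not met after ``max_iter`` calibration rounds.
    """
    he_panel_t, he_sub_t = diversity_targets
    n_loci = genome.n_loci
    ss = (rng_seed if isinstance(rng_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_seed))

    if he_panel_t <= 0:  # degenerate: every locus fixed, identical lines
        rng = np.random.default_rng(ss)
        hap = (rng.random(n_loci) < 0.5).astype(np.uint8)
        haps = np.tile(hap, (sum(group_spec), 1))
        labels = np.repeat(np.arange(len(group_spec)), group_spec)
        panel = FounderPanel(haps, labels)
        panel.achieved_he = {"panel": 0.0, "subgroup": 0.0}
        return panel

    # initial theta from E[2p(1-p)] = theta / (2 theta + 1) for p ~ Beta(theta, theta)
    theta = he_panel_t / max(1.0 - 2.0 * he_panel_t, 1e-6)
    f_sub = 0.4
    drift = np.full(len(group_spec), drift_other)
    children = ss.spawn(max_iter)
    panel = None
    for it in range(max_iter):
        drift[target_group] = f_sub
        rng = np.random.default_rng(children[it])
        panel = _draw_panel(rng, n_loci, tuple(group_spec), theta, drift)
        he_p = panel.marker_he(genome)
        he_s = panel.subgroup(target_group).marker_he(genome)
        panel.achieved_he = {"panel": he_p, "subgroup": he_s,
                             "theta": theta, "drift": drift.copy()}
        ok_p = abs(he_p - he_panel_t) <= 0.5 * rel_tol * he_panel_t
        ok_s = abs(he_s - he_sub_t) <= 0.5 * rel_tol * he_sub_t
        if ok_p and ok_s:
            return panel
        # multiplicative updates: panel He is monotone in theta,
        # subgroup He roughly proportional to (1 - F)
        theta = float(np.clip(theta * he_panel_t / max(he_p, 1e-6), 1e-3, 50.0))
        one_minus_f = np.clip((1.0 - f_sub) * he_sub_t / max(he_s, 1e-6), 0.02, 0.999)
        f_sub = float(1.0 - one_minus_f)

    he_p = panel.achieved_he["panel"]
    he_s = panel.achieved_he["subgroup"]
    if (abs(he_p - he_panel_t) <= rel_tol * he_panel_t
            and abs(he_s - he_sub_t) <= rel_tol * he_sub_t):
        return panel
    raise CalibrationError(
        f"unreachable diversity targets {diversity_targets}; "
        f"achieved panel He={he_p:.3f}, subgroup He={he_s:.3f}"
    )


def load_founders(path, genome: GenomeDefinition) -> FounderPanel:
    """Load a founder panel from a headered delimited genotype matrix.

    Rows are lines, columns are loci, values are haplotype alleles in {0, 1}.
    An optional leading ``group`` column gives subgroup labels.  Heterozygous
    or non-biallelic codes are rejected.
    """
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error) as exc:
        raise ValueError(f"empty or malformed founder genotype file: {path}") from exc
    if df.empty:
        raise ValueError(f"no founder records in {path}")
    if "group" in df.columns:
        groups = df.pop("group").to_numpy()
    else:
        groups = np.zeros(len(df), dtype=int)
    mat = df.to_numpy()
    if mat.shape[1] != genome.n_loci:
        raise ValueError(
            f"genotype matrix has {mat.shape[1]} loci, genome defines {genome.n_loci}"
        )
    if not np.isin(mat, (0, 1)).all():
        bad = np.unique(mat[~np.isin(mat, (0, 1))])
        raise ValueError(
            f"non-homozygous or non-biallelic genotype codes {bad!r}; "
            "founders must be fully homozygous lines coded 0/1"
        )
    panel = FounderPanel(mat.astype(np.uint8), np.asarray(groups))
    panel.validate(genome)
    return panel


def save_founders(path, panel: FounderPanel) -> None:
    """Write a panel as a headered delimited genotype matrix (see load_founders)."""
    df = pd.DataFrame(panel.haplotypes,
                      columns=[f"L{i + 1}" for i in range(panel.haplotypes.shape[1])])
    df.insert(0, "group", panel.group_labels)
    df.to_csv(path, index=False)


def write_map(path, genome: GenomeDefinition) -> None:
    """Write the sidecar map file: locus id, chromosome, cM, class, effect, favorable."""
    eff = np.zeros(genome.n_loci)
    eff[genome.qtl_indices] = genome.qtl_effects
    fav = np.full(genome.n_loci, -1)
    fav[genome.qtl_indices] = genome.favorable_allele
    cls = np.full(genome.n_loci, "SNP", dtype=object)
    cls[genome.qtl_indices] = "QTL"
    pd.DataFrame({
        "locus": [f"L{i + 1}" for i in range(genome.n_loci)],
        "chromosome": genome.chromosome,
        "position_cm": genome.position_cm,
        "class": cls,
        "effect": eff,
        "favorable_allele": fav,
    }).to_csv(path, index=False)
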