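# Methods

This note documents the simulation model, its parameters and defaults, the
numerical choices, what the synthetic founder generator emulates, and the
known limitations. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Trait architecture and genome

The genome defaults to 10 chromosomes of 160 cM (about 1600 cM total,
maize-like) with candidate loci on a uniform 0.1 cM grid. 1000 QTLs are
sampled with a minimum same-chromosome spacing of 0.2 cM; each receives an
additive effect β ~ N(0, 0.05 trait-units²) per allele copy, the favorable
allele being the one whose dosage increase raises the trait. 2000 loci
drawn from the remaining grid positions serve as neutral markers; all
prediction models observe markers only, never QTLs. Positions are in cM
within chromosome, loci are stored sorted, and dosages of homozygous lines
are coded {0, 2} (haplotypes {0, 1}).

Consequences of the uniform grid: the real SNP array the design emulates
has an irregular marker density and ascertainment-biased allele
frequencies; neither is reproduced. Expected heterozygosity (He) is always
computed on the 2000 markers unless QTLs are requested explicitly, since
markers are the observable locus set ("genome-wide diversity" is not
attributed to a specific locus set in the reference design).

## Synthetic founder panel

The generator emulates a structured dent panel of 338 fully homozygous
lines in three subgroups (82 / 57 / 199). Per-locus ancestral frequencies
are drawn from a symmetric Beta(θ, θ); each subgroup drifts away from them
under a Balding–Nichols model with subgroup-specific drift F; lines are
drawn locus-wise from subgroup frequencies and forced homozygous. θ and the
drift of the 57-line subgroup are calibrated iteratively (bounded
multiplicative updates, ≤ 15 rounds) so that realized marker He hits the
configured targets for the full panel and for that subgroup; the
calibration is deterministic under a fixed seed and fails loudly when
targets are unreachable (e.g. a subgroup more diverse than the Beta
maximum).

Two target conventions coexist on purpose:

- The generator's own defaults are (0.28, 0.13) — panel-level targets that
  the calibration check recovers within ±15% relative.
- The scenario engine requests (0.36, 0.30). The reference quantities
  0.283 / 0.133 describe diversity **at the end of burn-in**, and 20 years
  of recurrent phenotypic selection erode He by roughly half at the reduced
  scale (measured in dedicated burn-in pilots). Starting the panel higher
  lands the post-burn-in candidate pools in the intended regime, with the
  external:commercial diversity ratio ≈ 2 as in the reference design.

What the generator does not emulate: linkage disequilibrium within
subgroups beyond what drift induces (no pedigree structure), real map
clustering, or allele-frequency ascertainment. Passing tests therefore show
that the *method* behaves as designed under a realistic diversity
structure, not that any specific real panel would give the same numbers.

## Phenotypes

Phenotypes are line means over 4 environments in one year, y = TBV + ē with
ē ~ N(0, σ²_E/4), no genotype-by-environment interaction. σ²_E is fixed
once at simulation start as σ²_G0·(1 − r)/r with r = 0.4 interpreted at the
**single-plot** level and σ²_G0 the TBV variance among the founder panel;
the per-line-mean reading of r would replace σ²_E/4 by σ²_E and is not
used (a flag on `TraitModel` would be the place to change it). The
calibration is not revisited as genetic variance erodes.

## Meiosis and DH production

Crossovers follow a homogeneous Poisson process on the map (no
interference, no obligate chiasma), the process generating Haldane's
mapping function, so the transmitted phase along ordered loci is a Markov
chain with switch probability c(d) = (1 − e^(−2d/100))/2 between adjacent
loci. This is simulated exactly and vectorized; gametes are doubled into
fully homozygous DH lines. The same c(d) appears in the usefulness-
criterion algebra, so the meiosis simulator and the analytic cross-variance
predictions are mutually consistent — their agreement is the central
cross-module oracle test (10,000 DH, relative tolerance 8% ≈ 4 Monte-Carlo
standard errors of a variance).

## Genomic prediction

G-BLUP with a VanRaden relationship matrix G = Z_c Z_cᵀ/s, Z_c centered
with training-set allele frequencies and s = Σ 2p(1−p). The single variance
ratio is estimated by REML through the spectral decomposition of G
(computed from the SVD of Z_c, which is exact and cheap since the marker
count is far below the training-set size); profiling removes the error
variance analytically and a bounded 1-D optimization on the log ratio does
the rest. Marker effects are back-solved, â = Z_cᵀG⁺û/s (pseudo-inverse via
the same SVD), which makes G-BLUP exactly equivalent to ridge regression
with λ = σ²_e/(σ²_g/s) — asserted at 1e-6 relative against an independent
direct solve. The intercept is the phenotypic mean (exact, because Z_c has
zero column means and hence G·1 = 0); there are no cohort fixed effects
because simulated phenotypes have no year effects. Variance components are
re-estimated every year; a degenerate REML surface falls back to the
previous year's ratio (logged). Constant-phenotype training sets yield a
pure-intercept model rather than an error.

## UCPC and optimal cross selection

For homozygous parents, with s_j half the signed dosage difference and
B_jk = 1 − 2c_jk (block-diagonal over chromosomes, = e^(−2d/100) within),

- σ²_c = (â∘s)ᵀ B (â∘s),
- expected selected-fraction frequency at locus l:
  p_l = (z1_l + z2_l)/2 + i·h/(2σ_c) · s_l · (B(â∘s))_l, clamped to [0, 1],
- expected contribution of parent 1: ½ + i·h/(2σ_c) · mean_l (B(â∘s))_l,
  clamped to [0, 1]; contributions are computed over the effect-locus set.

These are normal-approximation (linear selection-response) results. Pilot
phase-tracked simulations (12 random crosses, 10,000 DH, top 5%) bound the
approximation error at ≤ 0.11σ_c for the selected mean and ≤ 0.017 for the
contribution; the oracle tests assert at 0.15σ_c and 0.03 plus 3 Monte-
Carlo SEs. The set objectives are V(nc) = the equal-weight mean of family
UCs (family sizes and within-family intensities are equal by design, and a
mean differs from a sum only by the fixed |nc|), and D(nc) = He of the
equally pooled selected-fraction frequencies.

The constrained problem (max V s.t. D ≥ He(t)) is solved by a
differential-evolution search on integer index vectors over the enumerated
candidate crosses: DE/rand/1/bin, population 60, CR = 0.9, F ~ U(0.4, 0.9),
budget 2000 generations or 200 stagnant generations, plus a 5% random-
immigrant move per trial (integer-vector DE alone loses population
diversity on set encodings and then fails on small instances), duplicate
indices repaired by random resampling, a greedy top-UC seed in the initial
population, feasibility-first ranking (any feasible set beats any
infeasible; infeasible sets ranked by violation). When no feasible set
exists the maximal-diversity set is returned flagged infeasible. Because V
is additive over families, an inactive constraint provably reduces the
optimum to top-UC selection, which the seed guarantees the optimizer
returns. Tie-breaks follow lowest candidate index. Exactness on toy
instances (≤ C(30,2) candidates, ≤ 3 crosses) is asserted against full
enumeration.

Bridging crosses maximize α·V* + (1 − α)·D* on the completed 20-cross set,
V*/D* min–max normalized by the max-V and max-D extreme sets found with the
same optimizer (α = 0.7 default, 0.3 as sensitivity variant); degenerate
normalization ranges zero the corresponding term with a warning. h = 1
throughout (the API accepts h < 1, no scenario uses it).

## Programs, scenarios and schedules

Both programs use a 3-year DH lag: year T recruits parents from cohorts
T−3, T−4, T−5. Burn-in is 20 years of phenotypic selection (first 3 years
random founder crossing; then the 50 best-phenotype progeny of the rolling
pool are randomly mated, with a within-family top-10% prestep in the
external program only). The external program (40 founders from the panel,
20 families × 40 DH/year, within-family fraction 10%, He* = 0.10 at
t* = 60) releases its best line per family every year; during burn-in the
release is by phenotype, afterwards by GEBV. Releasing during burn-in is
required for the 20-to-24-year donor access window to be non-empty before
year 21 — without it, direct-introduction scenarios would be identical to
the benchmark for two decades.

The commercial program (10 founders from the 57-line subgroup, 1600 DH/year
as 20 × 80 or, with bridging, 5 × 80 DE plus 15 × 80 E) considers per
scenario: benchmark ExE only under the declining He trajectory
(He* = 0.01, t* = 60); direct introduction with ExE ∪ DxE candidates under
constant He(t) = He⁰; bridging with ExE ∪ DExE breeding candidates (15
crosses) followed by 5 DxE bridging crosses under the weighted objective.
He⁰ is measured replicate-specifically on the candidate-parent pool at the
first post-burn-in year. Donor pools: the full 338-line panel, or released
donors aged 20–24 or 5–9 years. Donors are genotyped but never phenotyped
commercially; their GEBVs come from back-solved marker effects of the
commercial (or bridging/merged) model. Split-TS bridging fits separate
models on 3600 E and 1200 DE progeny; single-TS fits one model on all
4800. When no DE progeny exist yet (cold start) the bridging model falls
back to the elite model; when a donor window is empty the budget is kept
with next-best breeding crosses (both logged).

Randomness: one root seed per study; genome, panel and trait calibration
are study-level; each (replicate, program/scenario) pair gets an
independent child stream; all commercial scenarios of a replicate branch
from one burn-in state and read donors from the same external run, so
scenario contrasts are paired.

## Reduced desk design

The scaled-down study used by the ordering tests and the acceptance script:
3 replicates, 30 post-burn-in years, families of 20 DH, 400 loci (133 QTLs
+ 267 markers) on 10 × 100 cM, optimizer budget 250 generations (60
stagnant), population 40. The commercial within-family candidate fraction
is 10% (2 of 20) rather than the full-scale 5% (4 of 80): with one
candidate per family the diversity constraint is infeasible for years at
the reduced scale — an artifact of pool size, not of the method — and the
usefulness criterion consistently uses i(0.10). Metrics are reported on
the yearly E cohort (not the rolling pool); the rare-favorable set is fixed
per replicate at the end of burn-in (favorable-allele frequency ≤ 0.05).

What the reduced design shows: the qualitative contrasts (bridging vs
direct introduction by donor quality, the mid-term dip and later crossing
of direct introduction, the single-TS advantage, rare-allele dynamics,
constraint tracking) as orderings over replicate means. What it cannot
show: absolute gain magnitudes, full-scale accuracy levels, or 60-year
asymptotics.

## Known limitations

- Single additive trait; no dominance, epistasis, GxE or multi-trait
  extension; no heterozygous-parent (four-way) usefulness algebra.
- No crossover interference; chromosomes may transmit intact.
- The selected-fraction algebra is a normal approximation; its bias grows
  for very small families or extremely leptokurtic architectures.
- The DE optimizer is stochastic; optimality is only guaranteed (and
  asserted) on enumerable instances, elsewhere it is budget-bounded.
- VCF import and real SNP-array handling are out of scope; genotype I/O is
  plain delimited text plus a sidecar map.
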