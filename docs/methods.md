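# Methods

This note documents the models, defaults and numerical choices behind
`adipolipid`, and what the synthetic-data generators do and do not
emulate.

## Lipid nomenclature and classification

Species names follow the common shorthand `HEAD(chain[/chain...])` with
an optional `P-` (vinyl ether, plasmalogen class) or `O-` (alkyl ether)
prefix on the first chain; both `:` and the typographic `∶` separator
are accepted, and sphingoid `d`/`t` prefixes are parsed but treated as
ordinary chains. Single-token names such as `PC(34:1)` are sum
compositions: they carry total carbons/double bonds only and are
excluded from chain-specific calls (PUFA-containing, short saturated).
Parsing is reversible onto the canonical `:` dialect.

Classification defaults: a species is *PUFA-containing* when any single
chain has ≥ 2 double bonds (configurable; there is no universal numeric
definition of "PUFA-containing" at the species level); *short
saturated* when it has ≤ 1 double bond in total and ≤ 32 total carbons;
*phospholipid* when its headgroup is PC, PE or SM (the classes measured
in positive-ion-mode lipidomics; the set is configurable and defines
the total-PL normalization denominator). `P-` species are treated as
plasmalogen class on nomenclature alone — a deliberate assumption, as
computational parsing cannot supply the tandem-MS evidence that
confirms a vinyl ether.

Total-PL normalization divides each subject's column by that subject's
summed PC+PE+SM signal. Note the compositional consequence: the
normalized values are closed (they sum to 1 over phospholipids), so a
genuine increase of one abundant group necessarily depresses every
other species' fraction. This is a property of relative data, not an
artifact of the implementation; ground-truth recovery tests therefore
run on the raw simulated concentrations, where the generator defines
its truth, while the replay pipeline analyzes normalized fractions as a
study of relative composition would.

## Paired differential analysis

Discordant pairs contribute one observation per variable via the twin
normalization `log2(heavy/lean)`. The default test is the paired t on
log2 values (equivalent to a one-sample t on the twin log-ratios);
lipid abundances are heavy-tailed and approximately log-normal, so the
log scale is the default, with a flag to test raw fractions and a
Wilcoxon signed-rank alternative for distribution-free inference.
Species with any non-positive value cannot be log-transformed and raise
rather than silently dropping; all-zero difference vectors return the
degenerate (statistic 0, p = 1) branch with a warning.

Multiplicity control uses Storey q-values implemented in-package: the
null proportion is estimated by the fixed-λ tail estimator
`π̂0 = #{p > λ}/((1−λ)m)` at λ = 0.5 (a cubic-smoother variant over a
λ-grid is available behind a flag), clipped to (0, 1]; q-values follow
the step-up minimum rule and reduce exactly to Benjamini–Hochberg when
π̂0 = 1, which is the oracle used in the tests. Significance
conventions: q < 0.05 primary, q < 0.1 marginal.

One-way ANOVA (for multi-group designs such as knockdown time courses)
is classical between/within mean squares; zero within-group variance
returns (0, 1) when the means also coincide and (∞, 0) otherwise.

Partial least squares regression of twin-normalized lipid matrices on
twin-normalized fat cell size uses NIPALS PLS1: components are
extracted iteratively (w ∝ X'y, t = Xw, deflation of X and y), and
per-component explained variance in y is reported. The fit matches
scikit-learn's PLSRegression on dense problems; it is implemented
in-package so the algorithm is inspectable and dependency-light.

## Fatty-acid pathway activity indices

Desaturation/elongation activities are estimated as product/substrate
mol% ratios over a declarative step table shipped as package data
(`data/fatty_acid_steps.tsv`): Δ9 desaturation (16:0→16:1n7,
18:0→18:1n9; SCD), elongations 16:0→18:0 and 16:1n7→18:1n7 (ELOVL6),
the n-6 route 18:2n6→18:3n6→20:3n6→20:4n6 plus 20:4n6→22:4n6, and the
n-3 route 18:3n3→18:4n3→20:4n3→20:5n3→22:5n3→22:6n3. The C22:5/C20:5
ratio is taken in the n-3 series (the n-6 analogue is a separate row).
Ratios are indices of pathway activity, not kinetic rates: they are
invariant to whole-profile rescaling and multiply along chains, but
say nothing about absolute flux. Zero-substrate subjects yield NaN with
a warning rather than an infinite ratio, and steps with missing values
are dropped (with a warning) from the paired comparison.

## Dependency network inference

The network model is an undirected Gaussian graphical model in which a
missing edge means zero partial correlation. Because estimating
full-order partial correlations is hopeless at cohort-scale n, the
q-order approach tests ρ(i, j | Q) over many random conditioning sets
of size exactly q and summarizes each pair by its **non-rejection
rate**. Defaults: q = 3 (with n pairs in the teens, the test's
n − q − 2 degrees of freedom bound q severely), 500 samplings, per-test
α = 0.05, edge rule "tested positive in ≥ 55% of samplings"
(`rejection-rate`; the alternative `nrr-below` rule retains pairs with
NRR ≤ threshold and is selectable because the two conventions circulate
in the literature — both are recorded in the output metadata). Subsets
are drawn uniformly without replacement within a subset; subsets may
repeat across samplings. Partial correlations are computed by inverting
the (q+2)×(q+2) covariance submatrix, batched over samplings; the
computation is location/scale invariant.

**Choosing the per-test level.** The subset tests for one pair share
the same data, so the per-pair false-edge probability is approximately
the per-test α, not α to some power: at α = 0.05 an exploratory screen
of p variables admits ≈ 0.05·p(p−1)/2 spurious edges. That is
acceptable — and conventional — for hypothesis generation on a small
curated panel, which keeps the unadjusted default. For *structure
recovery* (benchmarks against known ground truth, or any analysis whose
product is the graph itself), divide the level by the number of tested
pairs: `pairwise_bonferroni_alpha(p, family_alpha)` with family_alpha
0.05 for accuracy benchmarks and 0.01 when exact recovery of the whole
graph is the claim (the per-replicate failure probability of exact
recovery equals the family-wise error rate, so the target exactness
dictates the family level).

Hubs are ranked by degree with lexicographic tie-break. Networks export
to GraphML and SIF with node type (L, FA, GE, clinical,
pathway_profile) and regulation (up/down/ns) attributes.

## Membrane analysis

The bilayer normal is fixed to z (planar bilayers; no director
fitting). The molecular order parameter at interior carbon i uses the
segment vector C(i+1)−C(i−1) — the common convention consistent with
numbering segments from the linkage end; terminal carbons carry no
value, and the convention is pinned by the magic-angle test
(θ = 54.7356° ⇒ S_mol = 0). Thickness is the separation of the mean z
of the two leaflets' head-reference atoms (density-profile definitions
need atomistic detail the geometric fixtures do not carry). Area per
lipid is Lx·Ly over the per-leaflet count and is exact on constant-box
trajectories. Standard errors use block averaging (5 blocks by
default) because consecutive frames are autocorrelated; the analysis
window discards a configurable equilibration period (40 ns of a 100 ns
trajectory in the replay defaults). Coordinates are assumed whole
(un-wrapped per molecule); the text trajectory format is a minimal
box+coordinates dialect documented in `membrane.write_trajectory`.

Mixture design uses largest-remainder rounding per leaflet, applied
symmetrically: e.g. 70 mol% PE of 128 lipids gives 45 PE + 19 PC per
leaflet (realized 70.3%).

## Synthetic-data generators

All generators are bit-reproducible given their spec (seed included).

**Twin cohort.** Log2 abundance = species baseline N(0, 1.5²) + pair
effect + residual N(0, noise_sd²) with the pair-effect variance set so
the within-pair correlation of log abundances equals the requested
value (default 0.5, an additive pair-level effect mirroring the strong
intra-pair similarity of adipocyte morphology). Defaults mirror the
study design: 13 discordant + 9 concordant pairs, 300 species, 10%
PUFA-ether species planted +1 log2 unit in heavy co-twins, 10% short
saturated species planted −1 log2 unit, noise sd 0.2. The planted
effect sizes are chosen for clear detectability at 13 pairs (the
motivating study reports direction and significance, not per-species
effect sizes). The `morbid` scenario applies an additional −1.5 log2
depletion of PUFA-ether species to every subject at identical cohort
geometry, so same-seed comparisons between scenarios isolate the
ether-lipid collapse. What the generator does *not* emulate: missing
values, batch/run-order drift, cross-species abundance correlation
beyond the shared pair effect, and compositional closure at the
instrument level — so passing tests demonstrate correctness of the
statistical machinery, not robustness to those real-data features.
Fatty-acid profiles are generated analogously around a typical adipose
composition (palmitate ~21 mol%, oleate ~43 mol%) with planted
heavy-twin effects reproducing the direction of the remodeling
signature (palmitoleic and arachidonic up; stearic, linoleic,
α-linolenic down), renormalized to 100 mol%.

**Gaussian graphical models.** Multivariate normal samples from a given
precision matrix (Cholesky sampling; positive-definiteness enforced),
with the true edge set read off the non-zero off-diagonal entries.
`random_sparse_precision` draws Bernoulli(density) support with
magnitudes uniform in (0.2, 0.3), random signs, and a diagonally
dominant rescaled-to-unit diagonal — placing direct partial
correlations in the detectable range at n of a few hundred while
keeping two-step indirect correlations (order strength²) below
detectability, the regime where conditional-independence recovery is
informative.

**Bilayer trajectories.** Chains are interleaved segment walks: carbon
positions are laid down so the measured segment vector at carbon i *is*
the drawn orientation vector, giving exact control of the order-
parameter distribution. Two orientation modes: `mixture` (aligned with
probability S plus isotropic, or in-plane with probability −2S for
negative targets — exact in expectation, Monte-Carlo noise in any
finite sample) and `fixed_angle` (deterministic polar angle
arccos(√((2S+1)/3)), so every segment attains the target exactly; the
noise-free limit used for closed-form checks and the parameter-recovery
grid, where a calibrated 2-sem criterion applied to many independent
stochastic quantities would fail by design a calibrated fraction of the
time). The lateral box realizes the target APL exactly (optionally
jittered per frame); head planes sit at ±thickness/2; with volume
coupling, thickness = 2·V_lipid/APL at fixed molecular volume (default
1.2 nm³, giving 4 nm at 0.60 nm²), so thickness × APL is constant and
thickness falls as the membrane spreads — the geometric origin of the
thickness–area anticorrelation. Waters, ions and atomistic detail are
not modeled; only the geometry the analysis operators consume.

## Problem sizes and determinism

The test suite and acceptance script run deliberately scaled problem
sizes chosen to make every check sharp at interactive runtimes: null
calibration over 200 cohorts of 100 species (the paired t on exactly
log-normal data is size-calibrated at any species count), planted
recovery over 20 default cohorts, network benchmarks at p = 20/n = 500
(20 replicates) and the chain graph at n = 1000, membrane grids at 64
lipids × 25 frames. The replay pipeline derives one seed per stage from
the master seed via SHA-256, writes all numeric output with a fixed
`%.10g` format, and is byte-identical across runs with the same
configuration; the manifest records the configuration hash for
provenance.

## Known limitations

- The species-level classifier trusts nomenclature; isobaric species,
  adducts and MS-level ambiguity are out of scope.
- No covariate adjustment or mixed models in the paired analysis; the
  design argument (genetic matching within pairs) carries that weight.
- NRR networks are undirected and say nothing about causality or sign
  of regulation beyond the attached differential annotations.
- The membrane module analyzes trajectories; it does not generate
  dynamics, and its synthetic fixtures cannot stand in for force-field
  physics (no chain packing constraints, excluded volume, or realistic
  per-segment saturation profiles).
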