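# adipolipid

Analysis toolkit for membrane lipidome remodeling in adipose tissue,
built around a monozygotic-twin study design: lipid-species-aware
differential lipidomics in BMI-discordant twin pairs, fatty-acid
desaturation/elongation activity indices, mixed-variable dependency
networks inferred from q-order partial correlations, and membrane
biophysical properties computed from bilayer trajectories. Every stage
can be exercised end to end on synthetic cohorts with known ground
truth.

## Who this is for

Lipidomics and systems-biology groups analyzing paired (co-twin,
case-matched) adipose tissue profiles who want a tested, reproducible
pipeline for:

- parsing lipid shorthand (`PC(P-16:0/20:4)`, `PE(16:0/20:4)`,
  `SM(d18:1/24:0)`, sum compositions like `PC(34:1)`) into headgroup,
  *sn*-1 linkage (ester / alkyl ether / vinyl ether plasmalogen) and
  chain composition, with PUFA- and saturation-aware classification;
- total-phospholipid normalization and paired differential testing with
  Storey FDR q-values;
- enzymatic pathway activity ratios (SCD, ELOVL6, ELOVL5, FADS1/Δ5,
  FADS2/Δ6, ELOVL2/4) from fatty-acid mol% profiles;
- undirected Gaussian graphical ("dependency") networks over lipids,
  fatty-acid ratios, gene expression and clinical variables;
- area per lipid, bilayer thickness and S_mol order-parameter profiles
  from membrane simulation trajectories.

## The statistics at the core

**Twin normalization.** Each variable is reduced to one value per
discordant pair, `X_norm = log2(X_heavy / X_lean)`, removing shared
genetic and early-environment variance. Differential species are called
by paired two-sided tests (t on log2 values by default, Wilcoxon
optionally) with Storey q-values: `π̂0 = #{p > λ}/((1−λ)m)` at λ = 0.5,
`q_i = min_{p_(j) ≥ p_i} π̂0 m p_(j)/j`; q < 0.05 is significant,
q < 0.1 marginal.

**Non-rejection-rate networks.** For each variable pair (i, j) the
package samples `n_samplings` conditioning sets Q of size q from the
remaining variables and tests H₀: ρ(i, j | Q) = 0 with the exact
transform `t = r·sqrt((n−q−2)/(1−r²))` on n−q−2 degrees of freedom. The
non-rejection rate (NRR) is the fraction of subsets where H₀ survives;
an edge is kept when the pair tested positive in at least a threshold
fraction (default 0.55) of 500 samplings. Low NRR ⇒ robust direct
dependency. For structure-recovery studies use
`network.pairwise_bonferroni_alpha(p)` as the per-subset level (see
`docs/methods.md`).

**Membrane properties.** Area per lipid `APL = Lx·Ly / n_leaflet`,
thickness as the head-reference plane separation, and the molecular
order parameter `S_mol(i) = ⟨(3cos²θ − 1)/2⟩` for the angle θ between
the segment vector C(i+1)−C(i−1) and the bilayer normal (z); frames
before the equilibration cutoff (default 40 ns of a 100 ns trajectory)
are discarded and standard errors use 5-block averaging.

## Worked example

Run the full synthetic twin-cohort analysis (13 discordant + 9
concordant pairs, 300 lipid species with planted PUFA-ether elevation
and short-saturated depletion in heavy co-twins):

```bash
adipolipid -q replay --seed 11 --out-dir out/
cat out/report.txt
```

```
adipolipid pipeline report
config hash: ee9828fd58c5410f

cohort: 300 species, 44 subjects, 13 discordant pairs

differential species (q < 0.05): 74 (30 up, 44 down); marginal (q < 0.1): 91
  PE(P-16:0/22:4): log2(heavy/lean) = +0.914, q = 8.19e-09
  PC(P-16:0/18:2): log2(heavy/lean) = +0.921, q = 8.19e-09
  PC(14:0/16:0): log2(heavy/lean) = -1.142, q = 8.19e-09
  ...
fatty-acid steps at p < 0.05: 8
  SCD_16: ratio heavy/lean log2 = +0.443, p = 4.21e-06
  ...
network: 53 nodes, 152 edges (rule rejection-rate, threshold 0.55, q = 3, 500 samplings)
  edge precision 0.553, recall 0.857 against generator truth
  hub pathway_down: degree 13
  ...
membrane systems (ranked by area per lipid):
  low_bmi: APL = 0.6000 +/- 0.0000 nm^2, thickness = 4.000 nm, PE 38/leaflet (realized 59.4 mol%)
  high_bmi: APL = 0.5950 +/- 0.0000 nm^2, thickness = 4.000 nm, PE 45/leaflet (realized 70.3 mol%)
```

Reading the report: all 30 planted PUFA-ether species come out
significant with direction "up" (log2 heavy/lean ≈ +1, the planted
effect), the planted short saturated species come out "down"; the
fatty-acid panel shows the planted Δ9-desaturation increase (SCD_16 up)
with its complementary elongation-ratio decreases; the 53-variable
network stage reports edge precision/recall against the generator's
known conditional-independence structure (exploratory settings, per-test
α = 0.05); and the two bilayer mixtures (59 vs 70 mol% ethanolamine
plasmalogen, mirroring the lean/heavy membrane compositions) recover
their designed areas per lipid exactly.

The same stages are available individually (`simulate`, `normalize`,
`diff`, `ratios`, `network`, `membrane`, `validate`) on your own
CSV/TSV tables; `adipolipid diff --help` etc. describe the file schemas.

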