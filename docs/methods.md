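# Methods

## The duplex-locus pairing models

At a marker that distinguishes the two subgenomes, a duplex allotetraploid
(G₁G₂N₁N₂) produces gametes in one of three classes — GG, GN, NN — whose
frequencies depend on how the four chromosomes pair. The five classical
models are stored as exact rationals (0:1:0, 1:2:1, 1:4:1, 3:8:3, 2:5:2).
Two of them carry independent enumeration oracles:

* *Random chromosome*: the three partitions of {G₁,G₂,N₁,N₂} into two
  bivalents are enumerated, each bivalent contributing one chromosome
  uniformly; restricting to the homologous partition reproduces the
  homolog-disomic row, restricting to the homeologous partitions the
  homeolog-disomic row.
* *Random chromatid*: all C(8,2) = 28 unordered pairs of the eight
  post-replication chromatids are enumerated; sister pairs model double
  reduction, and excluding them collapses the ratio back to 1:4:1.

The maximal-equational ratio 2:5:2 is stored without an oracle: its
derivation enumerates nine quadrivalent arrangement/separation
configurations that we do not reconstruct.

Progeny genotype distributions are convolutions of two gamete-class
distributions over allele dose (selfing: the F1 distribution with itself;
backcross: against the pure-NN tester). *Apparent heterozygosity* — the
fraction of progeny showing a band from each parent — is 1 − f₄ − f₀ under
selfing and 1 − f₀ in the backcross, since dosage is invisible to a
dominant-band marker.

## The preferential pairing factor

The continuous model indexes pairing behavior by p ∈ [0, 2/3] (0 = fully
random arm pairing, 2/3 = strict homologous bivalents; the bound comes from
1/3 of bivalent pairings being homologous a priori) and a double reduction
rate α. The balanced-gamete frequency is

    f_GN(p, α) = 2/9 + p/3 + 5/4·p² + 2/3·(2/3 − 3/2·p² − α·(2/3 − 3/2·p²)),

which at α = 0 simplifies to 2/3 + p/3 + p²/4 — strictly increasing, 2/3 at
p = 0, exactly 1 at p = 2/3. The double-reduction gamete frequency is
α·(2/3 − 3/2·p²). (The final quadratic coefficient inside the α bracket is
read as 3/2 so that the two expressions are mutually consistent and the α=0
simplification holds; the estimator below depends only on that reading.)

### Estimation from a backcross panel

In a backcross of the duplex F1 to the NNNN tester, only NN gametes from the
F1 are visible (as quadruple-homozygote progeny); GGNN and GNNN progeny are
indistinguishable. Two assumptions make direct estimation possible:

1. **Equal GG and NN gametes** (duplex symmetry): the unobservable GG count
   is set equal to the observed loss count, so from n scored progeny with
   `loss` losses the inferred gamete counts are NN = GG = loss,
   GN = n − 2·loss.
2. **Source of off-class gametes.** Under *bivalent-only*, all GG/NN gametes
   come from homeologous bivalents (α-term set to zero) and
   2/3 + p/3 + p²/4 = f_GN is solved for its positive root, clamped to
   [0, 2/3]. Under *quadrivalent double-reduction*, 3/8 of the off-class
   gametes are attributed to double reduction (the fraction expected when
   all quadrivalent configurations are weighted equally), which raises the
   effective target to 1 − (3/4)·(GG+NN fraction) before the same quadratic
   is solved. The two assumptions differ by only a few hundredths in p̂,
   with bivalent-only slightly smaller.

The estimate is closed-form (positive quadratic root), not EM over the
unobserved genotype classes. It is undefined when loss > n/2 (f_GN would be
negative); when 2·loss/n exceeds 1/3 the root falls below 0 and is clamped,
flagged via `in_range`.

### Likelihood-ratio test

The inferred gamete counts are treated as a multinomial over
{GN: f(p), GG: (1−f)/2, NN: (1−f)/2} and 2·(ℓ(p̂) − ℓ(p₀)) referred to
χ²(1). Against the natural null p₀ = 2/3 this is *degenerate* whenever any
loss was observed — f(2/3) = 1 assigns probability zero to the data — so the
result carries a DEGENERATE flag rather than an artificial p-value. Finite
statistics are produced for interior nulls.

## Panel statistics

* **Detection power.** P(no quadruple homozygote in n progeny) = (1 − q)ⁿ
  with q the model/design quadruple-homozygote frequency: q = 2/36 for
  selfing under random chromosome assortment (both GGGG and NNNN detectable)
  and q = 1/6 for the backcross. Each selfed individual is treated as one
  selfing round of a fully heterozygous parent.
* **Exact binomial CI.** Clopper–Pearson via beta quantiles
  (statsmodels `proportion_confint(method="beta")`); at k = n the lower
  bound has the closed form (α/2)^(1/n), which the tests use as an
  independent check.
* **Goodness-of-fit G-test.** G = 2·Σ o·ln(o/e), divided by the Williams
  correction q = 1 + (a² − 1)/(6·n·(a − 1)) before the χ²(a−1) tail. A zero
  expected probability facing a nonzero observed count is reported as
  degenerate.
* **Heterogeneity G.** Each marker's (het, non-het) counts against expected
  counts from the pooled proportion, df = (markers − 1)(classes − 1), no
  Williams correction. This equals Σ G_marker − G_pooled for any common
  expected ratio, which the tests verify by brute force. The published
  combination (Williams on the pooled test, none on the heterogeneity test)
  reproduces both printed statistics.
* **Outlier handling.** The panel retains the single individual accounting
  for six of the ten observed losses by default; `exclude_outlier`
  recomputes every statistic with the per-marker `n_loss_excl` counts, the
  recovered calls counting as heterozygous.

## Simulator

Gametes are drawn at the class level of the (p, α) model: GN with
probability f_GN, GG and NN with (1 − f_GN)/2 each, tagged within-class
compositions uniform. This is deliberate — the estimator's expected
frequencies are the ground truth the simulator must match, so no mechanistic
bivalent-configuration mode is offered (a natural mechanistic construction
has marginal GN frequency 2/3 + p/2, which disagrees with f_GN between the
endpoints). Genotypes that are not subgenome-duplex, which arise in selfed
lineages once a subgenome allele is lost, fall back to random chromosome
assortment of their four tagged alleles: preferential pairing between
subgenomes has no meaning for them. Loci are independent (the study design
used one marker per linkage group); linkage is out of scope.

Selfed lineages use single-seed descent (the line-maintenance method is
otherwise unstated) with defaults mirroring the study: 48 S-lines per cross
direction selfed to S₄, 43 or 35 surviving families, maternal sublines split
at the penultimate generation, three measured individuals per subline.
Phenotypes are mu + additive·(G dose) + dominance·(het loci) plus normal
family, maternal, and residual deviates. Real floral traits are not normal;
normality is the simplest structure satisfying the variance-based tests'
assumptions, so passing tests certify the estimators' arithmetic and
calibration under their own assumptions, not robustness to the real data's
shape. The backcross shortcut `simulate_marker_panel` draws loss counts
binomially at (1 − f_GN)/2, which is exactly the distribution induced by
per-individual simulation of the F1 × tester cross.

## Variance analyses

* **F-ratio test** s²_B/s²_A with two-sided p = 2·min(tail, 1 − tail).
* **Levene's test** centers on the group median by default
  (Brown–Forsythe), matching its use as a test "robust to asymmetry";
  mean-centering is available.
* **CV interval.** CV = 100·s/x̄, small-sample correction
  CV* = (1 + 1/(4n))·CV, normal-approximation CI
  CV* ± z·CV*·√(1/(2(n−1))). (The textbook formula this follows is cited in
  the source literature only by equation number; the implemented form is the
  standard one and is recorded here as a documented choice.)
* **Broad-sense heritability.** H² = (Var(F₂) − V_E)/Var(F₂); V_E defaults
  to the weighted form (V_P1 + V_P2 + 2·V_F1)/4 (each F₂ allele pair has two
  chances to be in the F1 configuration), with the unweighted three-class
  mean as an alternative. Negative H² is returned unmodified: it means no
  detectable segregational variance.
* **Nested variance components.** Family / maternal-within-family / residual
  by expected mean squares (method of moments) with Searle's coefficients
  for unbalanced data. Negative estimates are reported, not truncated —
  truncation would bias the percent-of-total decomposition and hide
  sampling noise; only the percentage column floors negatives at zero (so
  shares sum to 100). Standard errors use the large-sample Var(MS) ≈
  2·MS²/df propagation; significance is by F-tests against the next stratum
  down. REML was not used: the published analysis ran REML in commercial
  software, but moment estimators are transparent, match the published
  negative components, and are unbiased under the balanced designs simulated
  here.

## Problem sizes and numerics

Simulation-based checks use 200 replicate panels of 5,000 backcross progeny
for estimator recovery (tolerance ±0.02 on the mean), 1,000 binomial draws
per probability for CI coverage (threshold 0.93), 200 replicates of a
balanced 40 × 2 × 3 design for component recovery (±10% on means), and
n = 300 F₂ individuals for heritability recovery (±0.1). Tolerances on
recomputed published values are the printed precision of those values.
Distribution objects validate to 1 within 1e-12; the estimator's
forward/backward consistency is held to 1e-9; the GN frequency at p = 2/3 is
treated as exactly 1 in likelihood computations (a 1e-12 guard absorbs float
round-off).

## Limitations

* Single-locus theory throughout; no linkage, no aneuploidy, no chromosome
  rearrangements, no distinction between homeologous recombination and
  simple fragment deletion (the marker dichotomy cannot separate them).
* p and α are not jointly identifiable from the collapsed het/loss
  dichotomy; α enters only through the two fixed assumptions.
* The per-marker significance of p̂ against p = 2/3 is reported as
  degenerate rather than reproducing published significance codes whose
  null construction is not recoverable.
* Phenotype generation is normal and additive-plus-dominance; epistasis,
  maternal-by-family interaction, and non-normal trait distributions are not
  modeled.
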