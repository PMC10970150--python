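# Methods

This note documents the statistical models implemented in haplogeo, the
conventions and defaults chosen where the literature admits more than one,
and what the synthetic-data generator does and does not emulate.

## Data model

A locus is an aligned set of equal-length haploid sequences over
{A,C,G,T,-,N}; RNA `U` is mapped to `T` and IUPAC ambiguity codes other
than `N` are mapped to `N` on ingest (the workflow assumes clean Sanger
traces were selected upstream). Before any haplotype or diversity
computation, *complete deletion* removes every site carrying `-` or `N` in
any sequence, so all statistics for one dataset are computed on a common
set of fully resolved sites and two individuals share a haplotype iff
their cleaned sequences are identical. Haplotype labels H1…Hk are assigned
by descending overall abundance with ties broken by first occurrence,
which makes labelling deterministic under input reordering (up to
equal-abundance ties). Multi-locus analyses concatenate the cleaned
per-locus alignments over the shared sample set (organelle loci are
uniparental and non-recombining, so concatenation is the natural
treatment).

## Diversity

Observed haplotype diversity is the plug-in estimator `h = 1 − Σ pᵢ²`
without the `n/(n−1)` correction: the emulated survey's tables pin this
choice (a population of 3 with two haplotypes is printed as 0.4444, the
uncorrected value; the corrected one would be 0.6667). Nucleotide
diversity per site is the mean pairwise proportion of differing sites over
all unordered pairs. "Mean ± SD" rows across populations use the sample
SD (n−1 denominator) by default, with a flag for the population SD — the
source tables do not state their convention and only the mean is treated
as reproducible. The "Total" row pools all samples; for π a
mean-of-populations option exists because pooled and averaged totals
coincidentally agree in the emulated survey.

## Differentiation

**Gst / Nst.** Both use the Pons & Petit (1996) sample-size-unbiased
components with the harmonic mean ñ of per-population sizes over the K
populations with n ≥ 2:

    vS = ñ/(ñ−1) · (1/K) Σₖ Σᵢⱼ wᵢⱼ xₖᵢ xₖⱼ
    vT = Σᵢⱼ wᵢⱼ x̄ᵢ x̄ⱼ + vS/(ñK),      stat = (vT − vS)/vT

with wᵢⱼ = 1−δᵢⱼ for Gst and wᵢⱼ = (pairwise sequence distance between
haplotypes i and j) for Nst. When all off-diagonal distances are equal the
two are algebraically identical, which is exercised as a test invariant.
The Nst > Gst test permutes haplotype identities over the distance matrix
(frequencies fixed), destroying the association between haplotype
similarity and location; p-values use the (1 + #extreme)/(n_perm + 1)
convention, as do all permutation tests in the package.

**Hudson Fst.** `1 − Hw/Hb` with Hw and Hb the mean pairwise difference
counts pooled over within- and between-population pairs. Estimates are
reported as computed (possibly negative) in tables; only the IBD transform
clamps them at zero, keeping `Fst/(1−Fst)` monotone and finite.

**AMOVA.** One grouping level. Pairwise difference counts are treated as
squared Euclidean distances (the "number of different alleles" distance),
sums of squares follow Excoffier–Smouse–Quattro
(`SS = Σ d²/group size` within groups, total analogously), variance
components use the unequal-n coefficient
`n0 = (N − Σnₖ²/N)/(K−1)`, and `Φst = σ²ₐ/(σ²ₐ+σ²ᵦ)` is tested by
permuting individuals among populations. On a balanced two-deme design
with these distances, Φst coincides with Hudson's Fst to rounding — a
documented correspondence used as a cross-check between the two
independent code paths.

## Isolation by distance

Population coordinates are taken as printed decimal degrees (centroids of
the per-sample values); distances are great circles with Earth radius
6371.0 km. The regression is OLS of `Fst/(1−Fst)` on natural log
kilometres over unordered pairs, excluding pairs with Fst ≥ 1, undefined
Fst, or zero distance (counted and reported). Because the P(P−1)/2 pair
observations are not independent, the OLS slope p-value is reported side
by side with a Mantel permutation p on the same transformed matrices;
neither is privileged. The Mantel statistic is the Pearson correlation of
off-diagonal entries under joint row/column permutation of the second
matrix.

## Demography

**Tajima's D** uses the 1989 constants with `θ_W = S/a₁`; it is undefined
(NA) when S = 0, and the table-rendering layer prints monomorphic rows as
"0 (1)" to match the conventional report shape.

**Fu's Fs** is based on the Ewens sampling distribution of the number of
distinct haplotypes K at `θ = k̂` (mean pairwise differences):
`P(K=k) = |S₁(n,k)| θᵏ / Πᵢ(θ+i)` with unsigned Stirling numbers of the
first kind computed by exact integer recurrence and converted to logs
(exact for all n used; validated against rational-arithmetic enumeration),
and `Fs = ln(S′/(1−S′))`, `S′ = P(K ≥ K_obs)`.

**Simulated p-values.** Both statistics are ranked against constant-size
neutral panmictic coalescent samples conditioned on the plug-in θ
(S/a₁ for D, k̂ for Fs), simulated by a lightweight Hudson-style
coalescent in mutational time units (pair coalescence rate 1/θ, lineage
mutation rate 1/2). The primary tail is the lower (expansion) direction;
a two-sided option is exposed. Default 1000 replicates.

**Mismatch distributions.** The expected spectrum under sudden expansion
(size θ₀ → θ₁ at τ mutational units ago) is the exact two-epoch pair
solution: with `F̂ᵢ(θ) = θⁱ/(1+θ)ⁱ⁺¹` the stationary geometric spectrum
and β = (θ₁+1)/θ₁,

    Fᵢ = F̂ᵢ(θ₁)·[1 − PoisCDF(i; βτ)] + e^(−τ/θ₁) Σⱼ Pois(i−j; τ)·F̂ⱼ(θ₀),

truncated at the observed maximum difference count and renormalised. At
τ = 0 it reduces to the geometric spectrum; for θ₀ → 0 and large τ it
approaches a Poisson peak at τ. Fitting minimises
`SSD = Σ(obs−exp)²` by a coarse grid (θ₀ ∈ [0,100], θ₁ ∈ [θ₀,10⁴],
τ ∈ [0,100]) whose top basins are polished by Nelder–Mead; the SSD surface
is multimodal (θ₁ in particular is weakly identified when expansion is
strong), so multi-start refinement matters and θ₁ often sits at a bound
without degrading the fitted spectrum. Goodness of fit uses SSD and
Harpending's raggedness, tested by parametric bootstrap: samples of the
observed size are simulated under the fitted two-epoch coalescent, refit
(with a pruned grid), and the observed statistics ranked
(p = fraction ≥ observed; default 100 replicates).

**Raggedness convention.** `rag = Σ (xᵢ − xᵢ₋₁)²` with the spectrum padded
by a zero class at *both* ends, so a point mass gives 2 and the uniform
spectrum over 0..d gives 2/(d+1)². (The convention that omits the leading
step gives exactly half these values; the padded form is used consistently
for observed and bootstrap spectra, so the bootstrap test is invariant to
the choice.)

## Island model

`equilibrium_fst(Ne, ms, mu) = 1/(1 + 2Ne(ms+mu))` for a haploid
uniparental locus, and the two-marker ratio
`mu_over_ms(fst_cp, fst_mt) = (1/Fst_cp − 1)/(1/Fst_mt − 1) − 1` under the
assumption μmt ≈ 0. The algebraic round trip
`mu_over_ms(equilibrium_fst(Ne,ms,μ), equilibrium_fst(Ne,ms,0)) = μ/ms`
holds exactly and is property-tested. Outputs are reported at 4 decimals;
note that evaluating the ratio at inputs already rounded to 4 decimals
can differ from the unrounded computation by ~0.002 at the survey's
values, which is why a 0.01 tolerance is attached to the worked example.
Ne and ms are not separately identifiable from two Fst values and are not
estimated.

## Synthetic-data generator

The generator emulates the survey design: 29 demes with the field sample
sizes (3–30, total 447), two non-recombining haploid loci with different
mutation rates, symmetric island-model migration, and metadata on a
west–east transect. Genealogies come from msprime (ploidy 1, one tree per
locus); mutations are placed by the package itself — Poisson numbers per
branch, uniform sites on an A-filled ancestral sequence, random distinct
target base — i.e. infinite sites on a finite length, so multiple hits are
possible but rare at the default rates, matching the difference-count
statistics the pipeline consumes.

**Migration convention.** `migration_rate` is Wright's ms: the fraction of
a deme replaced per generation by seeds from the species-wide pool
(own deme included), so the backward per-lineage rate to each other deme
is ms/d. Under this convention the expected sequence-based Fst equals
`1/(1 + 2·Ne·ms)` for *any* number of demes, not only asymptotically,
which makes two-deme calibration experiments against the equilibrium
formula meaningful. Because Hudson's Fst is a ratio of coalescence times,
it is insensitive to μ under infinite sites; calibration experiments
therefore use μ ≪ ms (per-locus θ of order 0.1–0.2) so the identity-based
μ term in the formula is within Monte-Carlo error.

**Defaults as study conditions.** Ne declines linearly west→east
(7500 → 2500, mean 5000), reproducing the survey's west-rich diversity
gradient; ms = 1.3×10⁻⁴ puts 2·N̄e·ms ≈ 1.3 and overall Φst near 0.43;
per-site rates 1×10⁻⁷ (fast locus) and 1.5×10⁻⁸ give within-deme per-site
diversity ≈ 0.03 and ≈ 0.005 — the magnitudes of the emulated survey. A
default-seed dataset yields ≈60 haplotypes at the fast locus, overall
h ≈ 0.96 and Hudson Fst ≈ 0.47. What the generator does **not** emulate:
the real survey's much larger singleton haplotype load (its ~239
haplotypes reflect mutation-rate heterogeneity along the sequence),
alignment gaps/indels, geographic irregularity of deme placement, and any
selection or recombination. Passing tests therefore demonstrate
correctness of the estimators under the island-model coalescent, not
goodness of the island model for real *T. ciliata* data.

`simulate_expansion_sample` anchors the mutational-unit parameters to a
current size of 10⁴ (u = θ₁/2N); θ₀ = 0 is represented by a vanishingly
small ancestral size.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed (numpy `default_rng` /
msprime `random_seed`); the pipeline derives per-stage seeds from one
master seed via `SeedSequence.spawn`, and reruns with the same seed are
byte-identical. Defaults are 1000 permutations (Gst/Nst, AMOVA, Mantel),
1000 neutrality replicates, and 100 mismatch bootstraps. The test suite's
simulation studies use deliberately small designs — 200-replicate
calibrations of the two-deme Fst and of AMOVA null p-values, a
50-replicate τ-recovery study (median fitted τ within 25% of truth), and
3–6-deme pipeline datasets — sizes chosen so the whole suite documents the
statistical behaviour at interactive cost; all scale up linearly via the
same entry points.

## Known limitations

- One grouping level only (no region/population hierarchical AMOVA, no
  Φct/Φsc); the west/east split of the emulated survey is descriptive.
- The spatial (range-expansion) mismatch model, Fu & Li's D*/F*, and
  skyline-type inference are out of scope.
- Pairwise-deletion site handling is accepted as a policy flag but all
  shipped statistics use complete deletion.
- θ₁ of the expansion model is weakly identified when expansion is strong;
  interpret fitted θ₁ (often at a bound) with care, τ and θ₀ are the
  meaningful outputs.
- The IBD slope's OLS p-value ignores pair non-independence; use the
  Mantel p for inference.
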