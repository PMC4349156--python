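# Methods

## Models

### Λ-coalescents

A Λ-coalescent on `b` active ancestral lineages merges each fixed set of `k`
lineages at rate

    λ_{b,k} = ∫₀¹ x^{k−2} (1−x)^{b−k} Λ(dx) / Λ-normalisation ,

so the total rate of k-mergers is `C(b,k) · λ_{b,k}`.  Three families are
implemented:

* **Kingman** — `λ_{b,2} = 1`, no multiple mergers.  The binary-merger null
  derived from low-variance (Wright–Fisher-like) reproduction.
* **Beta(2−α, α)** — `Λ = Beta(2−α, α)`, `1 ≤ α ≤ 2`, giving
  `λ_{b,k} = B(k−α, b−k+α)/B(2−α, α)` (computed in log-space with `betaln`).
  α parametrises the tail of the offspring-number distribution: the
  probability of a family of k or more viable offspring decays like `k^{−α}`,
  so smaller α means heavier tails, larger mergers and a stronger singleton
  excess in the SFS.  `α = 2` is routed to the exact Kingman path: the
  Beta(0, 2) measure is degenerate and the limit of the rates is the Kingman
  rate (the `B(0,·)/B(0,·)` ratio is otherwise numerically indeterminate).
* **Point-mass (Dirac ψ)** — `Λ = δ_ψ`, `0 < ψ ≤ 1`, giving
  `λ_{b,k} = ψ^{k−2} (1−ψ)^{b−k}`.  ψ is the fraction of the population
  replaced by a single family in a sweepstakes event.  The pure point mass is
  used rather than the two-component (Kingman + point mass) construction:
  it is the form used by the minimum-distance inference framework this
  package implements, and it nests Kingman pointwise as ψ → 0.  Note the
  nesting is *pointwise in the rates*, not uniform in n: at `b` lineages the
  relative weight of triple mergers is `C(b,3)ψ(1−ψ)/C(b,2) ≈ bψ/3`, so for
  ψ = 0.005 and n = 100 a few percent of events are still multiple mergers
  and φ₁ sits ≈ 0.026 above the Kingman value.  ψ must be ≪ 1/n before the
  expected spectrum is indistinguishable from Kingman.

### Growth models

Exponential (rate β) and algebraic (rate γ) growth are modelled as
time-inhomogeneous Kingman coalescents with backwards relative population
size

    ν(t) = e^{−βt}   (exponential) ,   ν(t) = (1+t)^{−γ}   (algebraic) ,

and pair-coalescence intensity `C(b,2)/ν(t)`.  These forms are explicit
stand-ins: the growth-model literature the method descends from does not fix
a unique parametrisation, so the two canonical decay shapes were chosen and
are documented here.  Waiting times are drawn by inverting the cumulative
intensity in closed form (exact; no numerical root-finding), and `β = γ = 0`
reproduces homogeneous Kingman exactly, event for event.

Time is in coalescent units throughout.  No conversion to generations or
years is performed; the `N^{α−1}` time-scale discussion that motivates
multiple-merger models is deliberately out of computational scope.

### Expected spectra

The model-expected normalized SFS is `φ_i = E[L_i]/E[Σ_j L_j]`, where `L_i`
is the total length of branches subtending `i` of the `n` leaves.  For
Kingman (and exact Kingman equivalents) the closed form `φ_i ∝ 1/i` is used.
All other families use Monte Carlo over the block-counting process: at `b`
blocks, draw an exponential waiting time at total rate `Σ_k C(b,k)λ_{b,k}`,
pick `k` with probability proportional to `C(b,k)λ_{b,k}`, merge `k`
uniformly chosen blocks.  The batch engine accumulates per-class sums,
squares and cross-products, yielding delta-method standard errors for the
ratio estimator `mean(L_i)/mean(L_tot)`; φ is renormalized to sum to one
(closed form exact; Monte Carlo to 1e−9 after renormalization).  The engine
is JIT-compiled with numba when available (~10⁵ genealogies at n = 122 in a
few seconds) and falls back to pure Python otherwise.  Results are cached by
`(n, family, parameter, reps, seed)`.

Correctness is cross-checked three independent ways in the test suite: the
Kingman closed form, an exact enumeration of the block-size partition chain
at small n (expected visit probabilities × holding times), and msprime's
Beta-coalescent branch-length spectra at n = 20.

## Inference

### Minimum-ℓ² fitting

    ℓ²(θ) = Σ_{i=1}^{n−1} ( ξ_i/S − φ_i(θ) )² ,   ℓ₂ = √ℓ² .

The full class range enters, including zero-count classes (ℓ² needs no
positivity).  The parameter grid defaults to α ∈ [1.000, 2.000] and
ψ ∈ [0.005, 1.000] in steps of 0.005 — every estimate this method is
expected to print is a multiple of 0.005.  All grid points share one
Monte-Carlo seed stream so the ℓ² curve is smooth in the parameter rather
than re-randomized per evaluation; ties in the argmin break toward the
smaller parameter and set a `tie` flag.  The Kingman null ℓ²(0) is always
evaluated against the closed form and reported alongside.  Fits are
bit-for-bit reproducible given `(n, family, grid, reps, seed)`.

Default `reps = 100_000` per grid point suits one-shot analyses of a single
spectrum.  Replicated studies (parameter-recovery experiments, null
calibration) use `reps = 20_000` with a shared seed: the expected-spectrum
cache makes every fit after the first nearly free, and pilot runs show
recovery of α within ±0.05 in the mean at n = 122, S ≈ 90, 50 replicates.

### G test and approximate likelihood

With `E_i = S·φ_i`, adjacent classes are pooled from the right tail until
every pooled expectation reaches `pool_min`, then

    G = 2 Σ O ln(O/E)   over pooled classes with O > 0 ,
    df = #pooled − 1 − #fitted parameters ,

with a χ² tail probability (p flagged unavailable when df ≤ 0).  `pool_min`
defaults to **5** — Cochran's classical validity rule.  A threshold of 1
leaves dozens of expectation-≈1 cells at n = 122, S ≈ 90 and inflates the
nominal 5% level of the G test to ~13–14%; with the Cochran rule the
measured null rejection rate is within the binomial band of 5%
(`scripts/acceptance.py` recomputes it).  Threshold and pooling direction
are configurable.  Pooling preserves ΣO and ΣE exactly.

Two caveats the package makes explicit rather than hiding: (i) the χ²
reference treats the observed spectrum as a multinomial draw from φ — on
real single-locus data all S sites share one genealogy, which overdisperses
the spectrum and makes the G test anti-conservative; the null-calibration
check therefore draws multinomial spectra (a parametric bootstrap of the
test's own sampling model).  (ii) `approx_loglik` is the multinomial
log-likelihood `Σ ξ_i ln φ_i` up to an additive constant, with zero
Monte-Carlo cells floored at half the smallest positive φ (logged); model
rankings by Δlog-likelihood and by ΔG agree because both are the same
likelihood.

### Tajima's D significance

The summary layer reports the D statistic itself plus a two-tailed P from
the conventional generalized-beta approximation (D scaled to [D_min, D_max]
with mean 0, variance 1).  A simulation-based P is available by fitting
spectra simulated under a chosen coalescent null instead; the beta
approximation is the default because it requires no model choice.

## Statistics conventions

* **Missing data** — columns containing `-` or `N` in any retained ingroup
  sequence are excluded from `effective_length`, from S/θ_S, from haplotype
  counting and from the SFS (complete-case).  Pairwise quantities (K, π,
  F_ST, divergence) use pairwise deletion.  Both conventions are recorded in
  result objects so published tables computed with other software can be
  reconciled.
* **Coordinates** — 1-based inclusive column indices everywhere.
* **Polarization** — a single designated outgroup sequence; a site enters
  the unfolded SFS only when ingroup-biallelic with the outgroup carrying
  one of the two alleles.  Outgroup gap/N, outgroup third states and
  ingroup multi-allelic sites are dropped and tallied by reason
  (`polarization_log`); the accounting identity
  S = used + dropped is asserted in tests.  Sites polymorphic in deeper
  outgroup taxa or homoplasic on the outgroup lineage will polarize wrongly
  or drop — the package makes no probabilistic ancestral-state
  reconstruction.
* **F_ST** — Hudson's `1 − H_w/H_b` on nucleotide differences, with H_w the
  group-size-weighted mean of per-group mean pairwise differences and H_b
  the mean between-group difference; permutation P-values preserve group
  sizes, `P = (#{permuted ≥ observed}+1)/(n_perm+1)`, default 1,000
  permutations with the seed recorded.  Small negative estimates (order
  −1/group size) are expected for exchangeable groups.
* **D′** — haploid gametes (phase known); biallelic complete-case sites;
  singleton exclusion and strict `maf > maf_min` filters; `|D′| = |D|/D_max`
  with the standard frequency bounds.
* **Divergence** — D_XY is the Jukes–Cantor corrected mean between-group
  per-site difference; D_a subtracts the mean of the (also corrected)
  within-group diversities; the standard deviation is the delta-method
  variance `9p(1−p)/((3−4p)²L)`.
* **Mode detection** — strict local maxima after merging tied plateaus to
  their leftmost class; modes closer than `min_separation` (default 2)
  classes keep the higher peak.  This makes the visual "the spectrum is
  trimodal" criterion explicit and testable.

## Synthetic data

The generator produces data whose truth is known exactly, so every pipeline
stage is testable without downloads.

* **Mutation convention** — expected mutations = `(θ/2) ×` total branch
  length in coalescent units (the classical θ = 4Nμ convention halved for
  the haploid single-allele-per-individual setting), placed on branches
  proportional to length, each on a fresh column (infinite sites; at most
  one mutation per column, asserted exactly).  Under Kingman this gives
  `E[S] = θ·a₁`, which the tests verify against Watterson's formula.
* **Outgroup** — generated from the ingroup ancestral sequence with
  Jukes–Cantor equal-rates substitutions at event rate
  `−(3/4)ln(1−4d/3)` for target observed divergence d; multiple hits are
  allowed on the outgroup lineage only.  This produces realistic
  polarization failures (third states, mispolarized sites) at a low rate.
* **Balanced locus** — two *independent* within-haplogroup genealogies
  joined by `d_fixed` diagnostic columns fixed-different between the groups,
  each oriented derived-in-A or derived-in-B with equal probability.  This
  reproduces the genealogical argument for a long-standing balanced
  polymorphism — the balanced allelic classes accumulate variation as if
  they were isolated populations — without simulating selection forward in
  time.  Each sample independently (probability `swap_rate`) exchanges one
  contiguous block of diagnostic columns for the other haplogroup's alleles,
  emulating rare recombination between the classes as a single-block event;
  this displaces the high-frequency modes by small offsets, as in real data.
* **The documented preset** — n = 122 in haplogroups of 43 and 79, L =
  2,500, 20 diagnostic columns, within-haplogroup Beta(2−α, α) genealogies
  at α = 1.1 (strong sweepstakes singleton excess), `theta_within = 3.27`
  chosen once so the expected total S ≈ 87 given the measured mean total
  branch lengths (≈16.6 and ≈24.4 coalescent units at n = 43 and 79),
  swap_rate = 0.03, outgroup divergence 0.02 (about twice the within-species
  haplogroup divergence).  What the preset does *not* emulate: locality-level
  sampling noise within regions (haplogroups map to regions perfectly, so
  regional allele frequencies are 100%/0% rather than ~97%/92%), intra-locus
  recombination outside the diagnostic block, sequencing error, and indels.
  Tests passing on the preset therefore demonstrate the statistical
  machinery end to end, not robustness to those real-data features.

## Problem sizes used in the tests and acceptance script

Replicated checks run at the scales a single CPU handles in minutes:
Monte-Carlo expected spectra at 10⁵ genealogies for single comparisons and
2×10⁴ per grid point for replicated fits; 50 replicates per recovery point;
200 null spectra for calibration; 10⁴ genealogies for the waiting-time law;
500–1,000 alignment replicates for the mutation-convention checks at
n = 10–50.  These sizes were chosen so Monte-Carlo error is well below each
assertion's tolerance.

## Known limitations

* No Ξ-coalescents (simultaneous multiple mergers) and no recombination
  within simulated genealogies; the balanced-locus block swap is a
  phenomenological stand-in, not a crossover model.
* No confidence intervals on α̂/ψ̂ (grid point estimates only, matching the
  method implemented); no joint multi-locus inference; no HKA-style
  polymorphism/divergence test.
* The G test's χ² reference ignores genealogical overdispersion (above);
  treat single-locus G P-values as descriptive, not formal.
* Published-table reconciliation: effective alignment length after
  quality/gap exclusion, the exact F_ST estimator, and the n/(n−1) factor
  in haplotype diversity all differ between programs; the conventions here
  are stated above and recorded in result objects, but small discrepancies
  against tables produced by other software are expected.
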