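# mmcoal — multiple-merger coalescent inference from site-frequency spectra

`mmcoal` analyses nucleotide variation in **high-fecundity organisms** whose
reproduction may follow *sweepstakes* dynamics: highly skewed, heavy-tailed
offspring-number distributions under which the classical Kingman coalescent of
binary mergers breaks down and **multiple-merger (Λ) coalescents** become the
appropriate neutral null model.  It was built for the kind of study where a
candidate locus (e.g. a gene showing extreme spatial differentiation in
Atlantic cod) is tested for **balancing selection** against a
sweepstakes-aware null, using one consensus allele sequence per individual.

The package covers the full inference chain:

* **Alignment layer** (`mmcoal.io`) — FASTA alignments with per-sample
  locality/region/role metadata, haplogroup classification by a diagnostic
  site, segregating-site tables.
* **Summary statistics** (`mmcoal.stats`) — S, number of haplotypes H,
  haplotype diversity h, mean pairwise differences K, Watterson's θ_S,
  nucleotide diversity π, Tajima's D; Jukes–Cantor corrected gross/net
  divergence D_XY and D_a; Hudson's F_ST = 1 − H_w/H_b with a permutation
  test; pairwise |D′| linkage disequilibrium with singleton/MAF filters.
* **Site-frequency spectra** (`mmcoal.spectrum`) — unfolded spectra
  ξ_1..ξ_{n−1} polarized against a single outgroup sequence, folding,
  normalization, and mode detection.
* **Coalescent models** (`mmcoal.coalescent`) — Kingman,
  **Beta(2−α, α)** (1 ≤ α ≤ 2; α = 2 is Kingman), **point-mass (Dirac ψ)**
  (λ_{b,k} = ψ^{k−2}(1−ψ)^{b−k}), and exponential/algebraic growth models as
  time-changed Kingman coalescents.  Expected normalized spectra
  φ_i = E[L_i]/E[ΣL_i] come from the Kingman closed form
  φ_i ∝ 1/i or from a fast Monte-Carlo block-counting engine with
  per-class standard errors.
* **Model fitting** (`mmcoal.inference`) — minimum-ℓ² estimation:
  ℓ² = Σ_i (ξ_i/S − φ_i)² minimized over a parameter grid (default step
  0.005), always reporting the Kingman null ℓ²(0); likelihood-ratio G tests
  with right-tail pooling; approximate multinomial log-likelihoods.  The
  fitting core is a scikit-learn style estimator (`SpectrumModelFit`) with
  `fit`, `get_params`/`set_params` and fitted `*_` attributes.
* **Synthetic data** (`mmcoal.simulate`) — infinite-sites data under any of
  the coalescent models, and a two-haplogroup "balanced locus" scenario whose
  unfolded spectrum is trimodal (a singleton mode plus two high-frequency
  modes at complementary classes), the genealogical signature of long-term
  balancing selection.

## Worked example

Simulate the documented balanced-locus preset (n = 122 sequences of 2,500
sites in haplogroups of 43 and 79, 20 diagnostic sites, Beta(2−α, α)
within-haplogroup genealogies at α = 1.1), then run the pipeline:

```bash
mmcoal simulate --preset ckma --seed 786 --out-dir demo
mmcoal sfs demo/alignment.fasta demo/metadata.tsv --outgroup outgroup --out-dir demo
mmcoal sumstats demo/alignment.fasta demo/metadata.tsv --groups all,region --out-dir demo
mmcoal fit demo/sfs.tsv --families beta,dirac --reps 20000 --seed 1 --out-dir demo
mmcoal report demo
```

The report (abridged) prints:

```
Observed SFS: n=122, S=105
  modes (class, count): (1, 54), (44, 12), (5, 5), (78, 3), (11, 2)

Model fits:
  beta: param=1.345, l2=0.01853, l2(0)=0.1303, G=59.62 (df=7, p=1.80e-10)
  dirac: param=0.06, l2=0.02483, l2(0)=0.1303, G=61.60 (df=8, p=2.26e-10)
```

and `demo/sumstats.tsv` / `demo/fst.tsv` contain:

```
group   n    S    H   h       K        theta_S   pi        tajima_d
all     122  106  55  0.9604  13.9403  0.007885  0.005576  -0.9479
North   79   84   42  0.9623  5.1217   0.006801  0.002049  -2.3408
South   43   17   13  0.8051  1.6855   0.001572  0.000674  -1.8284

comparison   fst     p_perm    n_perm
North|South  0.8448  0.000999  1000
```

Reading these numbers: the unfolded spectrum is **trimodal** — a singleton
excess (54 of 105 sites) plus modes at classes 44 and 78, the complementary
high-frequency classes produced by the two divergent haplogroups (43 + 79 =
122).  Both multiple-merger families fit far better than the Kingman null
(ℓ² of 0.019/0.025 against ℓ²(0) = 0.130) because they capture the singleton
mass, yet the G tests still reject both — no exchangeable-population
coalescent predicts the two balanced high-frequency modes, which is exactly
the signature of balancing selection.  Regional F_ST ≈ 0.84 with permutation
P < 0.001, while Tajima's D is strongly negative *within* each region.

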