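# Methods

## The model

`ldcall` treats a sequenced diploid individual as the output of a
three-level generative process.

1. **Founder chains.** For each parent, a left-to-right HMM over `K`
   latent founder haplotypes walks across the `n` SNP loci. The state
   `f_i` is the founder being copied at locus `i`; transitions
   `P(f_{i+1}|f_i)` model historical recombination between founder
   lineages and are estimated per locus (the chain is inhomogeneous — LD
   decays at different rates along the chromosome). Emissions
   `P(h_i|f_i)` give the allele copied from that founder, absorbing
   mutation and panel noise. The maternal chain `M` and paternal chain
   `M'` are independent (random mating); they may have different `K` and
   are usually the same trained model when one panel describes both
   parental populations.

2. **Genotype.** `g_i = h_i + h'_i` with alleles coded 0/1, so genotype
   1 is heterozygous.

3. **Reads.** Each allele observation at locus `i` carries an error
   probability `ε = min(10^(−q/10), 1/2)` from its Phred quality `q`.
   Conditional on `g_i`, a read factor is `1−ε` (homozygote matching the
   read), `ε` (homozygote mismatching), or exactly `1/2` (heterozygote:
   sample the matching chromosome and read it correctly, or the other
   chromosome and mis-read it — `(1−ε)/2 + ε/2`). Factors multiply over
   the reads covering the locus; a mapping confidence `m(r) ∈ (0,1]`
   raises the read's factor to the power `m(r)`, after which the products
   are likelihood weights rather than probabilities. Reads carrying an
   allele absent from the panel are dropped on ingestion. Reads spanning
   several SNPs are decomposed into independent per-SNP observations,
   consistent with the model's one-SNP-per-read emission assumption.

The `ε ≤ 1/2` cap is a deliberate guard: a base with `q = 0` would
otherwise have error probability 1 and become (anti-)informative.

## Inference

The exact multilocus argmax of `P(g | r, M, M')` is NP-hard, so calls are
made by **posterior decoding**: compute `P(g_i | r)` for every locus from
one forward–backward sweep, call `argmax_g` independently per locus, and
optionally no-call loci whose maximum posterior is below a threshold `t`.

The sweep runs over the factored state `(f, f')`. The joint read emission
at locus `i` is

    phi_i(f, f') = sum_g L_i(g) * gamma_i(f, f', g),
    gamma_i(f, f', g) = sum_{h + h' = g} P(h|f) P(h'|f'),

with `L_i` the genotype-likelihood triple (a zero-coverage locus has
`L_i = (1,1,1)` and stays in the model — imputation of uncovered sites is
the method's point). Each transition step contracts the maternal chain
first and the paternal chain second (`T' A T''` as two matrix products),
costing `O(K²K' + KK'²)` per locus instead of the naive `O(K²K'²)`; the
naive Kronecker-product recurrence is retained as an internal cross-check
and the two are asserted equal to 1e−12 relative in the tests.

Numerics: each forward slice is renormalised and the log of the scaling
constants accumulates into `log P(r)`; the backward pass reuses the same
scale factors, so `sum_{f,f'} alpha_i beta_i = 1` at every locus. The
forward table is kept both before and after multiplying in the locus
emission, so the genotype marginal

    P(g_i, r) ∝ sum_{f,f'} pre_i(f,f') * L_i(g) gamma_i(f,f',g) * beta_i(f,f')

counts the locus-`i` emission exactly once. The normative check on all of
this is an exhaustive-enumeration oracle (sum over all `4^n` haplotype
pairs, `n ≤ 8`) which the fast route must match to 1e−9 absolute; the
tests run it on over a hundred random instances.

Tie-breaks are deterministic everywhere: an exact posterior tie goes to
the genotype with the larger data-free model prior, then to genotype 0.

## Training

Baum–Welch with per-locus expected counts, vectorised across panel
haplotypes. Choices the estimator leaves open, and the defaults taken:

- **Initialisation**: rows are uniform mixed with 10% of a Dirichlet(1)
  draw — near-symmetric but seed-reproducibly broken. Optional restarts
  (`n_restarts`, default 1) keep the best final log-likelihood.
- **Stopping**: log-likelihood gain `< 1e−6` or 100 iterations.
- **Pseudocount** `1e−6` on every expected count before renormalisation,
  so no emission is exactly zero — a zero emission would veto any read
  carrying the unseen allele and can make the forward pass lose all mass.
  Expected counts are clipped at zero against round-off, and a founder
  state with no occupancy at all (possible with pseudocount 0) falls back
  to a uniform row.
- `K = 7` founders by default; `K` trades model capacity against the
  `O(nK³)` decoding cost and the amount of panel data available.

EM monotonicity (trace non-decreasing within 1e−8) and seed determinism
are asserted in the tests.

Genotype priors for the single-SNP baseline come from the panel, by
default Hardy–Weinberg from smoothed allele frequencies (pseudocount 1);
direct genotype counting over consecutive haplotype pairs is available as
`mode="count"` for panels whose rows are ordered by individual.

## Baselines

- **Single-SNP Bayesian caller**: `posterior(g) ∝ L_i(g) P(G_i = g)` per
  locus — the same read model, no LD.
- **Exact binomial test**: call heterozygous when both alleles are covered
  (≥ 1 read each, relaxed from the stricter ≥ 2 used by some pipelines)
  and a two-sided exact binomial test of the minor-allele count against
  p = 1/2 does not reject at α = 0.01; otherwise call the majority
  homozygote; no coverage, no call. The literature this test descends
  from does not fully pin down the statistic; this implementation is the
  documented variant used throughout the package.

## Synthetic data

The generator mirrors the model's own assumptions, which is what makes
the end-to-end tests informative about correctness of the inference
machinery: founders are iid Bernoulli(1/2) haplotypes; panel haplotypes
copy a founder, switch founders with probability 0.01 per locus and flip
alleles with probability 0.005 (defaults); individuals draw two distinct
panel rows (drawing with replacement could return the same row and yield
a fully homozygous "diploid"); coverage is Poisson per SNP (mean 6 by
default, the regime where LD matters most); qualities default to constant
Phred 20, configurable as a discrete distribution; `ref_bias` skews which
chromosome a heterozygous-site read samples (0.5 unbiased, 0.63
reproduces the reference-bias regime seen in some real platforms).
Downsampling keeps reads Bernoulli-independently, or exactly and nested
across fractions (`exact=True`), matching how coverage-titration subsets
are built.

What the generator does **not** emulate: real LD structure (hotspot-punctuated
recombination maps), allele-frequency spectra, quality-score
miscalibration, correlated errors within a read, mapping artifacts, indels
and multiallelic sites. Passing the synthetic benchmarks therefore
demonstrates that the estimator and decoder are correct and that LD
integration helps when LD exists — not that any particular accuracy will
be achieved on a given real dataset.

## Benchmark problem sizes

The standard study used by the tests and `scripts/acceptance.py` is a
1000-SNP, 120-haplotype panel with 10 true founders, one sequenced
individual, and Poisson-6 / Poisson-20 Phred-20 read sets — large enough
that concordances are stable to a point or two while the whole suite runs
in well under a minute. Oracle equivalence uses `n ≤ 6`, `K, K' ≤ 3`
(enumeration is `O(4^n)`); the recurrence cross-check uses `n = 20`,
`K = 5`.

## Known limitations

- Posterior decoding maximises per-locus marginals; the returned vector
  can be jointly inconsistent (it is a heuristic for an NP-hard argmax).
- The caller consumes pre-summarised pileups; it does not read BAMs or
  re-align, and paired-end structure is ignored.
- No phasing of the sequenced individual is attempted, and `K` is fixed
  by the user rather than selected automatically.
- Panels must be phased, biallelic and autosomal; unphased panel
  genotypes are rejected, not phased in-package.
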