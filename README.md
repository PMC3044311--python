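# ldcall

LD-aware genotype calling from low-coverage shotgun sequencing pileups.

Low-coverage shotgun sequencing often samples only one of a heterozygous
SNP's two alleles, so callers that look at each site in isolation miss many
heterozygotes. `ldcall` recovers them by borrowing strength across sites:
linkage disequilibrium (LD) learned from a phased reference panel makes the
reads covering nearby SNPs informative about the site in between — even a
site with no reads at all.

The package is aimed at developers and students of statistical genotype
callers: it bundles the LD-aware caller, two LD-oblivious baselines, a
seeded synthetic-data generator and an evaluation harness, so the whole
method can be exercised and benchmarked without any external data.

## Model

Each parental haplotype is modelled as a mosaic of `K` latent founder
haplotypes: a left-to-right hidden Markov model with per-locus parameters

- initial distribution `P(f_1)`,
- transitions `P(f_{i+1} | f_i)` (recombination between founders),
- emissions `P(h_i | f_i)` (the allele copied, with mutation/error noise),

trained on a phased panel with Baum–Welch. Two such chains — maternal `M`
and paternal `M'`, independent under random mating — form a hierarchical
factorial HMM: at locus `i` the chains emit alleles `h_i` and `h'_i`, the
genotype is `g_i = h_i + h'_i ∈ {0, 1, 2}`, and the reads covering the
locus are observed through likelihoods `P(r_i | g_i)` built from per-base
Phred qualities (for a read reporting allele `a` with error `ε`: factor
`1−ε` / `ε` for the matching / mismatching homozygote and exactly `1/2` for
the heterozygote; a mapping confidence `m(r)` exponentiates the factor).

Finding the jointly most probable multilocus genotype in this model is
NP-hard, so `ldcall` uses posterior decoding: a scaled forward–backward
pass over the factored state `(f, f')` computes every marginal
`P(g_i | all reads)`, and each locus is called by argmax, optionally
no-calling loci whose maximum posterior falls below a threshold. The
factored transitions let each step marginalise one chain at a time, giving
`O(m + nK³)` total work instead of the naive `O(m + nK⁴)`.

## Worked example

```python
import ldcall as lc

cfg = lc.SimConfig(n_snps=500, n_panel_haplotypes=60, n_founders_true=8,
                   mean_coverage=4.0, seed=11)
panel, _ = lc.simulate_panel(cfg)

result = lc.FounderHMM(panel, K=7).fit(seed=0)     # Baum-Welch training
h, hp, g = lc.simulate_individual(panel, seed=12)  # diploid truth
reads = lc.simulate_reads(g, cfg, seed=13)         # 4x Phred-20 pileup

calls = lc.LDGenotypeModel(result.hmm, reads).fit(threshold=0.0)
print(calls.summary())
print(lc.concordance(calls.genotypes, g).summary())
```

prints

```
LD-aware genotype calls (posterior decoding)
==============================================
loci:                500
founders (K, K'):    7, 7
total log-likelihood: -915.4133
no-call threshold:   0.0
call rate:           1.0000
calls 0/1/2:         125 / 252 / 123
no-calls:            0

Genotype concordance report
====================================
evaluated loci:       500
call rate:            1.0000
overall concordance:  0.9520
homozygous:           0.9667
heterozygous:         0.9385
confusion (rows truth 0/1/2; cols called 0/1/2/no-call):
     116       5       0       0
       9     244       7       0
       0       3     116       0
```

At a mean mapped coverage of only 4x the LD-aware caller still recovers
93.9% of heterozygous genotypes, because sites whose second allele was
never sampled are rescued by the posterior mass flowing along the founder
chains from their neighbours. `lc.compare_methods(...)` reproduces the same
numbers for the single-SNP Bayesian caller and the exact-binomial baseline
for a side-by-side table, and `lc.tradeoff_curve(...)` maps the
concordance gain available by no-calling low-posterior sites.

The same pipeline is scriptable from the shell:

```bash
ldcall simulate --config sim.yaml --out-prefix study
ldcall train --panel study.hap --legend study.legend --K 7 --seed 0 --out model.json
ldcall call --model model.json --pileup study.pileup.tsv --out calls.tsv
ldcall evaluate --calls calls.tsv --truth study.truth.tsv
```

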