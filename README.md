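# aimeval

How many SNPs does it take to measure the ancestry of a genome?

Panels of ancestry informative markers (AIMs) — SNPs with strongly skewed
allele frequencies between continental groups — are widely used in
biomedical, forensic and consumer genetics to estimate the biogeographical
ancestry of an individual from a few dozen to a few hundred markers.
`aimeval` is a simulation pipeline for quantifying how the **size** and
**informativeness** of such panels determine the accuracy of individual
ancestry estimates, relative to the "genome ancestry" obtained from the
full marker set.

The package provides:

- **Simulation** of differentiated source populations under the
  Balding–Nichols model (population allele frequency
  `p_k ~ Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)` around an ancestral
  frequency `p`, with drift parameter `F_k`), plus artificial admixed
  "AA-genomes" built by per-locus donor copying in fixed expected
  proportions, and controllable missingness.
- **Ancestry estimation** under the admixture likelihood
  `l_i(q) = sum_l [ g_il ln(sum_k q_ik f_kl) + (2-g_il) ln(sum_k q_ik (1-f_kl)) ]`
  by accelerated EM — supervised (ancestral frequencies `F` fixed from
  labelled references) or unsupervised (joint `Q`, `F`), with entry-wise
  cross-validation to choose the number of clusters `K`.
- **Marker informativeness**: per-locus Weir–Cockerham two-population
  F_ST, locus-specific branch lengths
  (`LSBL_a = (d_ab + d_ac - d_bc)/2`), panel LSBL summaries
  (accumulated and average per branch) and greedy LSBL-balanced AIM
  selection.
- **Panel evaluation**: random-SNP (rSNP) resampling across panel sizes,
  fixed-panel evaluation, subsample-size bootstrap experiments, RMS error
  of panel estimates about the genome-ancestry reference, and the
  size–error correlation.
- **Structure checks**: identity-by-state similarity and classical-MDS
  "PCA" coordinates.

PLINK PED/MAP text files and a simple TSV matrix dialect are supported for
genotypes; AIM panels are plain lists of SNP identifiers.

## Worked example

Three continental-scale source populations (drift 0.15, 50 individuals
each, 5,000 loci), random panels of 1,000 vs 100 SNPs resampled 50 times,
and equal-thirds admixed hybrids:

```python
import numpy as np
import aimeval as av

cfg = av.SimulationConfig(L=5000, K=3, n_per_pop=50, divergence=0.15, seed=7)
freqs, ref = av.simulate_dataset(cfg)
fhat = av.estimate_frequencies(ref)
hybrids = av.make_aa_genomes(ref, n_hybrids=20, seed=8)

summaries = av.rsnp_resampling(ref, fhat, panel_sizes=[1000, 100],
                               n_reps=50, seed=9)
for s in summaries:
    if s.group == s.ancestry:
        print(f"{s.group:6} {s.panel_size:5d} {s.mean:6.2f} {s.sd:5.2f}  "
              f"[{s.ci_low:.2f}, {s.ci_high:.2f}]")

q_aa = av.supervised_ancestry(hybrids, fhat).Q
print("hybrid mean ancestry (%):", np.round(q_aa.Q.mean(axis=0) * 100, 2))
```

prints

```
POP1    1000  98.87  0.16  [98.56, 99.16]
POP2    1000  98.88  0.21  [98.43, 99.17]
POP3    1000  98.76  0.17  [98.47, 99.14]
POP1     100  94.60  0.92  [92.59, 96.09]
POP2     100  94.81  1.15  [92.50, 96.78]
POP3     100  94.57  0.99  [92.06, 96.00]
hybrid mean ancestry (%): [33.39 32.64 33.97]
```

Each row is the replicate-level summary of the own-ancestry percentage of
one population at one panel size: with 1,000 random SNPs individuals
recover ~99% of their own ancestry with little replicate-to-replicate
spread, while 100-SNP panels lose several points of accuracy and show a
much wider spread — the dependence of ancestry inference on marker count
that the package is built to measure.  The hybrid genomes recover their
expected equal thirds (~33.3% per component).

A command-line interface mirrors the library
(`aimeval simulate | estimate | lsbl | evaluate | pca`); each subcommand
writes plot-ready TSV.

## Further reading

`docs/methods.md` documents the model and its assumptions, the numerical
choices in the EM solver, what the synthetic data does and does not
emulate, and known limitations.
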