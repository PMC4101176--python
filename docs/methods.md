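# Methods

## The estimation problem

An individual's genome ancestry is modelled with the standard admixture
likelihood.  Individual *i* carries a vector `q_i` on the K-simplex: the
proportion of its genome derived from each of K ancestral populations.
Each ancestral population *k* has a reference-allele frequency `f_kl` at
locus *l*.  Assuming Hardy–Weinberg equilibrium within ancestral
populations and unlinked loci, each of the two allele copies at locus *l*
is a reference allele with probability `p_il = sum_k q_ik f_kl`, so the
genotype `g_il` (coded 0/1/2 copies of the reference allele) contributes

    g_il * ln(p_il) + (2 - g_il) * ln(1 - p_il)

to the log-likelihood.  Missing genotypes are simply skipped; an
individual is scored on its called loci only.

Two fitting modes are provided:

- **Supervised** (`supervised_ancestry`): `F` is fixed, usually from
  labelled reference populations via `estimate_frequencies` (counts over
  called alleles, clamped into `[1e-6, 1 - 1e-6]` so fixed loci keep the
  likelihood finite).  The problem separates by individual and each row
  of `Q` is maximised independently.
- **Unsupervised** (`unsupervised_admixture`): `Q` and `F` are maximised
  jointly by EM from a seeded random start (`Q` rows ~ Dirichlet(1), `F`
  ~ Uniform(0.05, 0.95)); cluster labels are arbitrary and
  `align_clusters` resolves label switching by optimal assignment on the
  population-by-cluster mean-membership matrix before any comparison with
  truth.  A multi-start option keeps the best of several local maxima;
  the default is a single start.

## Numerical details of the solver

The EM update for a `Q` row multiplies each component by the average of
its posterior responsibilities and renormalises; it keeps rows on the
simplex exactly and never decreases the likelihood.  Plain EM, however,
approaches near-boundary optima geometrically slowly — at genome scale it
can need thousands of iterations and still sit 0.1–1 log-units short.
The supervised solver therefore accelerates EM with per-row SQUAREM
extrapolation carried out in **log space**: two EM steps give a step
vector and its curvature in `log q`, a per-row step length
`alpha = -|r|/|v|` extrapolates along them, and the result is
exponentiated back onto the simplex.  Log-space extrapolation matters
because the EM map is multiplicative: a geometric approach to the
boundary becomes linear in `log q`, positivity is automatic, and no
component can be absorbed at an exact zero (an absorbing fixed point of
the multiplicative update) when the row optimum is interior.  Three
safeguards keep the scheme trustworthy:

- a per-row adaptive cap on `alpha` (doubled after a successful capped
  step, shrunk after a failed one);
- a monotonicity fallback — any row whose extrapolated likelihood falls
  below the plain double-EM iterate keeps the latter, so the recorded
  log-likelihood trace is non-decreasing by construction (a property the
  test suite asserts on every fit);
- log coordinates clamped at `1e-12`, below which a component is
  indistinguishable from zero in the likelihood.

Convergence is declared when the total log-likelihood changes by less
than `tol * n_samples` (default `tol = 1e-6`), i.e. an absolute
per-individual tolerance.  A relative criterion is deliberately avoided:
at genome scale `|loglik|` is of order 10^6 and a relative threshold stops
far short of the per-individual optima.  Individually converged rows are
frozen and removed from the working set, so late iterations only touch
stragglers.  Solutions agree with independent per-row Nelder–Mead
optimisation to ~1e-3 log-units and with an exhaustive 0.01-step simplex
grid on small instances.

The unsupervised fitter uses plain joint EM (same update for `Q`, plus
`f_kl <- expected reference draws / expected total draws`) with the
conventional relative stopping rule `|Δloglik| < tol * |loglik|`
(default `1e-6`, `max_iter = 2000`); it is used where moderate precision
suffices and the monotone-trace property is the main guarantee.

## Choosing K

`cross_validation_error` partitions the *non-missing genotype entries*
(not individuals) into folds, hides one fold at a time, refits the
unsupervised model, and scores the hidden entries by squared error
against the model prediction `2 * sum_k q_ik f_kl`.  `choose_k` returns
the K with the lowest average error, ties going to the smaller K; fold
assignment is shared across K so the comparison is paired.  CV refits
default to `tol = 1e-5`, `max_iter = 600`: noticeably under-converged
fits at the true K inflate its CV error and can flip the selection to
K+1, so the CV defaults are deeper than a casual fit would need.

## Marker informativeness

Pairwise differentiation uses the Weir & Cockerham (1984) two-population
θ with the full variance components (sample sizes and observed
heterozygosity), per locus and as the multi-locus ratio of summed
components.  Negative per-locus estimates are reported as computed.
Locus-specific branch lengths decompose the three pairwise distances
among populations (a, b, c):

    LSBL_a = (d_ab + d_ac - d_bc) / 2   (cyclically for b, c)

Additivity `LSBL_a + LSBL_b = d_ab` holds exactly before clamping;
negative branches are then clamped to zero (branch lengths are
nonnegative) and counted, so diagnostics can report how many loci were
affected.  Panel summaries report accumulated and average (accumulated /
panel size) LSBL per branch over the loci actually present.
`select_aims_lsbl` grows a panel greedily: at each step the branch with
the smallest accumulated LSBL receives the unused locus with the largest
value on that branch, ties broken toward the smaller index; the resulting
per-branch totals differ pairwise by at most one selected locus's value.

## Panel evaluation experiments

"Genome ancestry" — the supervised estimate from the full marker set —
serves as the reference that every panel is judged against; evaluating
the all-loci panel reproduces it bit-exactly.

- `rsnp_resampling` redraws random panels of each requested size
  (default 500 replicates), records the population mean of the focal
  ancestry component per replicate, and summarises over replicates:
  mean, SD, percentile (2.5–97.5) interval and min–max range, in
  percent.  For labelled source populations the focal component is their
  own ancestry; for groups without a matching ancestry label (admixed
  hybrids) every component is reported.
- `evaluate_panel` runs a single fit on a fixed panel (intersected with
  the data; the effective size is recorded) and summarises across
  individuals instead — there is no replicate axis for a fixed panel.
- `panel_error` is the per-component RMS deviation of panel estimates
  about the reference values, on the proportion scale — an "error about
  the genome ancestry" rather than about the replicate mean (the latter
  is available from the resampling summaries).
- `sample_size_experiment` first removes profiles with call rate below
  0.9 (the conventional quality threshold for small panels), estimates
  ancestry once on the panel, then draws subsamples of individuals
  without replacement (default sizes 5–40 in steps of 5, 1,000 draws per
  size) and reports the mean of the subsample means with a percentile
  bootstrap interval.
- `size_error_correlation` is the Pearson correlation between panel size
  and error, per ancestry and pooled; constant inputs yield NaN with a
  warning rather than a fabricated value.

The 95% intervals throughout are percentile intervals of the replicate
(or subsample) distribution; no normality is assumed.

## Synthetic data: what it emulates and what it does not

`SimulationConfig` defaults encode the study conditions: three source
populations of 50 individuals, Balding–Nichols drift 0.15 per population
(continental-scale differentiation; ~0.005–0.01 emulates closely related
groups), ancestral frequencies uniform on (0.05, 0.95), no missingness
unless requested.  The drift parameter may be scalar or per-population.
Admixed AA-genomes partition loci among sources by largest-remainder
rounding of the target proportions (ties to the lower population index)
and copy each locus's genotype from one donor per source population per
hybrid, so each hybrid's expected — indeed realised, up to rounding —
ancestry equals the target proportions.

Deliberately not modelled: linkage disequilibrium and ancestry tracts
(every locus is independent, so there is no block structure for admixed
genomes), mutation, ascertainment bias of real SNP arrays, genotyping
error beyond missingness, and uniparental markers.  Tests passing on this
generator therefore validate the estimation machinery and the
size-accuracy relationships under the model's own assumptions; they do
not certify performance on real array data, where LD makes nearby SNPs
redundant and effective panel sizes smaller than nominal ones.

Genotype-level (not haplotype-level) copying is used for hybrids; with
unlinked loci and Hardy–Weinberg sources the two choices induce the same
expected ancestry and nearly the same likelihood geometry.

## Degenerate inputs and conventions

- `MISSING` is `-1`; 0 is a valid genotype and never doubles as a
  missing code.
- PED reference alleles are the first allele observed in file order;
  `0 0` or half-missing pairs are no-calls.  A PED file cannot record
  which allele the counts refer to, so written PED round-trips exactly
  only when each locus's first called genotype carries the reference
  allele; the TSV dialect round-trips unconditionally.  Any consistent
  coding yields identical likelihoods up to relabelling.
- Individuals with zero called loci get uniform membership, with a
  warning; loci uncallable in a population get frequency 0.5, with a
  warning; F_ST loci with fewer than two called samples in either
  population are excluded from the overall ratio and flagged per locus.
- IBS similarity is `1 - |g_i - g_j| / (2 L_joint)` over jointly called
  loci; pairs with fewer than 10 joint loci are flagged.  "PCA on IBS" is
  classical MDS of `1 - IBS` with a fixed eigen-sign convention
  (largest-magnitude loading positive).

## Known limitations

- The per-individual MLE at genome scale is not always within 0.5% of the
  vertex: with 20,000 independent loci and drift 0.15, a few per cent of
  unadmixed individuals have interior optima around 98.9–99.4% own
  membership (verified with an independent optimiser).  Saturating to
  "100%" for every individual requires far denser marker sets.
- Unsupervised mode uses a single EM start by default; for difficult
  data, increase `n_starts`.
- No standard errors on `Q`; no linked-locus or penalised variants of the
  admixture model.
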