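# Methods

## The model

`rarecoal` models the joint distribution of *rare* derived alleles across
populations under a demographic model shaped as a rooted population tree.
Each branch `b` is a panmictic population of constant scaled diploid size
`lambda_b = N_b / n_ref`; join events merge one branch into another
backward in time, and the surviving branch may change size at the join.
Time is measured in coalescent units of `2 n_ref` generations, with
`n_ref = 20,000` diploids as the internal scaling constant.  Conversion to
real units uses a per-generation per-site mutation rate
`mu = 1.25e-8` and a generation time of 29 years:
`years = t_scaled * 2 n_ref * 29`, `diploids = lambda * n_ref`.  The
per-site mutation rate per scaled time unit is
`theta_scaled = 2 n_ref mu = 5e-4`.

The data are site-pattern histograms: for every genomic site, the vector
of derived-allele counts per population, tracked up to a total count of
`max_m = 4` (the default), with a monomorphic class and an overflow class
for sites whose total derived count exceeds `max_m`.

Assumptions: no migration or admixture between branches, constant size
within each inter-join branch segment, neutral unlinked biallelic sites,
known ancestral alleles.  These match the scope of the tree-fitting
method; admixture is handled only descriptively by the allele-sharing
pipeline.

## The likelihood engine

The probability that a site shows pattern `m = (m_1..m_K)` is

```
p(m) = theta_scaled * [prod_k C(n_k, m_k)] * E[singleton time]
```

where the *singleton time* is the expected length of the genealogy branch
subtending exactly the carriers: looking backward, the `m_k` derived
lineages must coalesce among themselves down to a single lineage before
any of them coalesces with a non-derived lineage; the expected time that
single lineage survives (until it meets a non-derived lineage) is the
window in which the mutation can have occurred.  Configurations in which
a derived lineage meets a non-derived lineage earlier are absorbed as
inconsistent with the pattern.

Numerically, the engine exploits a factorization: between demographic
events, the pair `(a_b, n_b)` of derived and non-derived ancestral
lineage counts in branch `b` is a small continuous-time Markov chain
(rates `a(a-1)/2lam`, `n(n-1)/2lam`, and an absorbing `a n / lam`), and
chains in different branches are *independent*.  The joint state
therefore factorizes exactly into per-branch matrices `F_b[a, n]`,
convolved at joins.  No expectation approximation and no time
discretization are needed:

* within an epoch, `F(t)` is advanced by uniformization (series
  tolerance `1e-12`, chunked at `q dt <= 40` for stability);
* the epoch integrals `int P(a=1) dt` (the singleton-time contribution)
  and the absorbed masses come from exact triangular solves of
  `G M0 = F_end - F_0`, with a first-moment correction for the
  rate-zero states;
* after the last join, the remaining expected singleton time has a
  closed form by first-step analysis:
  `E(1,1) = lam`, `E(1,n) = 2 lam / (n(n+1)) + ((n-1)/(n+1)) E(1,n-1)`,
  and a two-term recursion for `a >= 2`.

Patterns that subtend *all* sampled lineages have an unbounded expected
subtending length (the root stem) and are rejected.

Exposed views keep the classical description available: the state object
reports the joint distribution over derived configurations (the product
of per-branch marginals) and the expected non-derived count per branch.
The engine reproduces the neutral single-population spectrum
`E[xi_i] proportional to 1/i` to machine precision and agrees with a
structured-coalescent Monte-Carlo oracle (msprime) within Monte-Carlo
error on multi-population trees, including trees with a query branch and
ancient (frozen) samples.

### Monomorphic and overflow classes

The composite likelihood is a multinomial over site classes:
`p_0 = 1 - theta * E[L]` for the monomorphic class, where `E[L]` is the
expected total genealogy length, computed exactly from per-branch
lineage-count distributions (pure-death chains, independent between
joins, convolved at joins; the root epoch uses the closed form
`E[L | k lineages] = 2 lam H_{k-1}`); the overflow class is the
complement `1 - p_0 - sum p(m)` floored at `1e-12`.  Linearizing the
no-mutation probability (`1 - theta L` instead of `E[e^{-theta L}]`) is
consistent with the per-pattern linearization and accurate to
`O((theta L)^2) ~ 1e-5` here.

### Restricted (shared-pattern) likelihoods

For single-sample placement, the histogram is restricted to variants
shared between the query and the reference panel (query-private calls
have high false-positive rates in low-coverage data and are excluded).
The default restricted likelihood keeps the classes
`{each shared pattern} + {everything else}`, using the pre-restriction
callable total; this retains the information in the *rate* of shared
sites, which is what separates deep from shallow merge points.  A
conditional mode (renormalizing over the shared classes only) is also
provided; it compares only the sharing profile across populations.

## Ancient samples (freezing)

A branch with sample age `t_a > 0` contributes nothing between the
present and `t_a`: its derived counts sit inertly in the configuration
and its factor enters at the activation time.  No singleton time accrues
while any carrier branch is frozen (a mutation cannot subtend a lineage
that does not yet exist).  An age of exactly zero takes the ordinary
path; a vanishing age agrees with it to numerical precision (tested).

## Inference

Sizes are fitted on log scale; each join time is parameterized as a
positive increment above the latest event on either child lineage, so
any in-bounds vector yields a valid tree ordering.  Maximization is
Nelder-Mead with perturbed restarts (stop when the improvement is below
`1e-4` log units).  Posteriors come from random-walk Metropolis with a
flat prior on the transformed scale inside the bounds
(`log lambda` in `[log 1e-3, log 1e3]`, increments in `[1e-8, 2]`); the
global proposal scale is tuned toward a 30% acceptance rate during the
first 20% of the chain and, from halfway through burn-in, the proposal
covariance is re-estimated from the chain history (adaptive Metropolis);
everything is frozen after burn-in, so the retained chain is a standard
Markov chain (detailed balance is verified on a discrete target).
Summaries are posterior medians and central 80% intervals.

Incremental tree building (`add_population`) grafts a new branch onto
each candidate branch, fits the attachment time and new-tip size, and
ranks candidates by likelihood.  When a free join time would cross a
*fixed* join, the proposal is rejected through validation (likelihood
`-inf`); with all times free this cannot happen.

## The simulator

All Monte-Carlo machinery is msprime/tskit-backed.  The default
histogram generator simulates truly unlinked sites: independent
genealogies, each carrying a small block (default 10) of iid sites whose
mutation status is Bernoulli(`1 - e^{-theta T}`); with the default
`theta` this leaves roughly 0.5-1% of variant pairs sharing a genealogy,
a negligible departure from the multinomial sampling that the composite
likelihood assumes.  A linked mode (recombining sequence at 1e-8 per bp,
binary mutations at `mu`) exists for pipeline tests and VCF export; its
clustered genealogies inflate the sampling noise well above multinomial,
so the unlinked mode is the one used for calibration experiments.
The VCF exporter relabels the binary states as A/C and shifts positions
to the 1-based convention; re-ingesting the VCF through the
mask-filtered histogram builder reproduces the simulated histogram
exactly (tested).

## Validation designs and problem sizes

The test suite runs desk-scale versions of the study-style experiments;
sizes were chosen by power analysis (expected log-likelihood gaps
`N * KL` between the true model and the nearest confusable alternative),
never tuned on test outcomes.

* **Oracle agreement**: two populations, 4+4 haploids, join at 0.002
  (sizes 1 and 0.5, ancestral 2.0), 1e5 replicates, every tracked
  pattern within 3 Monte-Carlo standard errors.
* **Five-population recovery**: nested tree with joins at
  0.002/0.0035/0.005/0.008 (4,600-18,600 years), tip sizes 0.5-1.2
  (10,000-24,000 diploids), 20 haploids per population, 1e6 unlinked
  sites, all 13 parameters free.  Point recovery is attempted by
  Nelder-Mead plus MCMC medians; posterior calibration is measured as
  central-80% coverage over 10 seeds.  A Cramer-Rao analysis of this
  design (multinomial Fisher information of the 126 site classes) shows
  best-possible standard errors of 150-950% for the recent-split times
  and sizes at 1e6 sites - the information simply is not there at this
  scale, since the original experiment used three orders of magnitude
  more sequence.  The point-tolerance check is therefore expected to
  fail and is kept as an honest negative; the coverage check is the
  meaningful calibration statement at this scale (about 80% observed).
* **Placement**: tip self-placement uses a three-population tree with
  strong drift (tip sizes 0.15, joins at 0.010/0.020), 16 haploids per
  population and 5e5 sites per replicate; per-replicate expected
  log-likelihood margin ~9 against the nearest wrong branch.  The
  clade-ancestor case mirrors the ancient-sample result: a query that
  split from the three-population clade ancestor (at 0.0268) before a
  distant outgroup joins (0.036) must map onto the ancestral branch;
  segment-level resolution costs ~6e6 sites for a decisive margin, so
  one replicate is run at that size.
* **Ancestry fractions**: two sources split at 0.02 (~23,000 years),
  panels of 60 haploids each, queries at 6x coverage with 0.1% per-read
  error and a >= 2-read carrier rule, 6e5 unlinked sites (~2,000 panel
  sites of allele count 1..9).  Anchor groups of 5 individuals define
  the 0%/100% axis; held-out pure and 40%-admixed individuals are
  recovered within ~15% per sample (1 s.e.), and the symmetric design
  keeps the ratio-of-counts nonlinearity far below the noise.

## Known limitations

* No migration, admixture edges, or within-segment growth; the tree is
  a scaffold, and admixed populations distort its times and sizes.
* The composite likelihood ignores linkage; on recombining data the
  posteriors are overconfident in proportion to the local tree
  correlation.
* The panel is assumed to have exact genotypes; only the query side
  models read noise, and query carriers are coded heterozygous.
* Sharing-ratio errors: per-stratum ratio curves use sqrt-count
  propagation with numerator and denominator treated as independent;
  the projection f = N/(N+I) uses a site-clustered variance
  (`sum_i (a_i - f T_i)^2 / (sum T_i)^2`), since the alleles of one
  called site enter the counts together; it reduces to the binomial
  rule f(1-f)/(N+I) when every called site carries a single shared
  allele.  Anchor-group uncertainties are the empirical standard errors
  of the group means.
* Synthetic validation covers idealized data: clean polarization, no
  sequencing batch structure, no reference bias.  Passing these tests
  demonstrates correctness of the machinery, not robustness to real
  ancient-DNA artifacts.
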