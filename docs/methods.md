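# Methods

## The measurement and the statistical problem

A 4C-seq library asks one question of one genomic location: which
restriction fragments of the genome were ligated to the bait fragment when
chromatin was cross-linked?  After digestion (EcoRI primary; MseI or DpnII
secondary), circularization and inverse PCR from the bait, sequencing reads
are aligned and assigned to the restriction fragments of the primary
digest.  The observation is therefore a count vector `n_1 .. n_K` over the
K fragments of the genome, with total `N = sum n_i`.

Because any single fragment's share of the library is tiny (K is in the
10^5–10^6 range for a mammalian genome; here desk-scale synthetic genomes
keep K in the hundreds), raw ratios `n_i / N` are noisy at low counts and
undefined structure at `n_i = 0`.  The package treats the counts as a
multinomial sample of an underlying composition and estimates that
composition in a Bayesian framework.

## The multinomial-Poisson / Dirichlet model

Independent Poisson counts conditioned on their total are multinomial; the
two models give identical inferences about the proportions, so the
estimator works on the conditional multinomial.  With a symmetric Dirichlet
prior of per-fragment mass `gamma` the posterior is
`Dirichlet(n_1 + gamma, ..., n_K + gamma)`.

Fold change is the natural effect-size scale for contact frequencies, so
expectations are taken of the *log2* proportions:

    elog2p_i = E[ log2 p_i | n ],   p ~ Dirichlet(n + gamma)

estimated from M Monte-Carlo instances of the posterior.  For browser
display the expectation is mapped back to linear space and multiplied by an
arbitrary integer scale S: `value_i = round(S * 2^elog2p_i)`.

Parameters, defaults, and why:

| parameter | default | meaning |
|---|---|---|
| `gamma` | 0.5 | per-fragment prior mass; the Jeffreys-style minimally informative symmetric choice for a multinomial. Configurable because the reference-prior literature admits several constructions; the closed form below covers any `gamma`. |
| `instances` (M) | 128 | Monte-Carlo posterior instances for routine tracks; validation uses 10^4. |
| `seed` | — | fixes the estimates bit-for-bit; replicate r uses `seed + r`. |
| `scale` (S) | 10^6 | arbitrary integer scale for browser values. |
| `q` | 0.10 | call quantile: "strongly positive" = top 10% of interacting sites. |

A useful identity checks the whole machinery: for a Dirichlet with
parameters `a_i`, `E[ln p_i] = psi(a_i) - psi(sum a)` (psi = digamma).  The
package never uses this closed form in the estimator — it samples — and the
tests use it as the independent oracle.  One consequence worth knowing: for
an all-zero count vector the expectation is `(psi(gamma) - psi(K gamma)) /
ln 2`, which by Jensen's inequality lies strictly *below* `-log2 K`; the
posterior mean of a log is not the log of the posterior mean.

### Sampling scheme

Dirichlet instances are generated as normalized gamma variates.  The
default sampler draws the joint uniform cube with a scrambled Sobol
sequence and maps each fragment's coordinate through the gamma inverse CDF
(randomized quasi-Monte-Carlo).  This is unbiased and reduces the error of
the log2-proportion expectations by roughly two orders of magnitude at
equal M compared with independent gamma draws — the worst measured mean
absolute deviation from the digamma closed form at M = 10^4 is ~7e-4 log2
units, versus a plain-MC standard error of ~0.03 for a zero-count fragment
at `gamma = 0.5`.  Plain sampling remains available (`method="gamma"`).

Numerical guards: inverse-CDF inputs are clipped to `[1e-12, 1 - 1e-12]`
and gamma variates floored at the smallest positive double, so log2
proportions are always finite.  Every sampled instance satisfies
`sum p_i = 1` to 1e-9.

A note on monotonicity: with the same seed and fixed (N, K), fragments with
higher counts receive higher `elog2p` with overwhelming probability at the
default M, but this is a statistical property of shared draws, not a
pathwise algebraic guarantee; the test asserts it at a fixed seed.

## From reads to counts

Reads are filtered to unique alignments, deduplicated by (chromosome, 5'
position, strand) — a sequence-free surrogate for duplicate removal — and
assigned to the fragment containing their 5' coordinate, because 4C reads
begin at ligation junctions.  Reads on chromosomes absent from the library
are counted in an `unplaced` tally, never silently dropped, so
`sum n_i + unplaced = retained reads` exactly.

The bait fragment dominates any 4C library through self-ligation without
carrying contact information, so it is masked from the statistical
universe; a configurable radius extends the mask to the surrounding cis
zone.  The library default is radius 0 (bait only); the shipped synthetic
scenarios mask ±1 Mb, standard 4C practice, because the distance-decay zone
next to the bait is reproducibly strong in every replicate yet
uninformative about specific long-range contacts.

Coverage tracks for ChIP-style reanalysis extend each unique read 3'-ward
to the library fragment length L and scale per-base coverage to a fixed
depth (default 20 million reads), so total signal mass is
`target * L`.  Extensions are clipped at coordinate 0; the mass identity
holds exactly for reads whose extension stays on the chromosome.

## Calling, intersection, binning

* **Strong calls**: exactly `floor(q * |universe|)` fragments with the
  highest `elog2p`, where the universe is fragments with `n_i >= 1` outside
  the mask ("interacting sites").  Boundary ties break deterministically by
  higher count, then lower genomic coordinate.
* **cis/trans**: a call is cis iff it shares the bait's chromosome.
* **Replicate intersection**: by fragment identity (all replicates share
  one library); a proximity mode merges calls within a tolerance into
  regions first.  Intersection is symmetric, associative, and a subset of
  every input.
* **Distance strata**: cis calls are stratified by the gap between
  fragment and bait intervals (<=50 kb, <=1 Mb, >1 Mb by default).
* **1 Mb binning**: fragment counts are summed into the bin containing the
  fragment midpoint (half-open bins, boundary midpoints go up), conserving
  the total, and proportions are re-estimated on the binned counts with the
  same Dirichlet machinery.

## qPCR quantification

All Ct arithmetic assumes quantity `∝ E^-Ct` with per-cycle amplification
factor E (2.0 when no standard curve is supplied, in which case efficiency
correction reduces to plain delta-Ct):

* standard curve: `E = 10^(-1/slope)` of Ct vs log10 input; replicate Cts
  at equal input must agree within 2 cycles; slopes shallower than |1| are
  rejected as non-exponential.
* digestion QC: percent digested `= 100 (1 - E^-(Ct_dig - Ct_undig))`;
  the protocol's acceptance line is >= 96% at every assayed site (at E = 2
  that is a delta-Ct of log2(25) ≈ 4.64 cycles).
* 3C relative frequency: `E_t^-Ct_t / E_r^-Ct_r` against a
  ligation-independent reference amplicon (XPB/ERCC3), with an optional
  per-primer random-ligation (BAC) correction factor.
* nucleosome occupancy: delta-delta-Ct with the arithmetic mean of the two
  reference-gene Cts (geometric mean of quantities — the symmetric choice
  when the protocol specifies only dual-gene normalization); protection
  fold is mutant over control.
* McrBC allele selection: post-digestion signal `maternal + retention x
  paternal`; maternal purity below 0.9 flags incomplete paternal removal.

Group comparisons use the two-sample two-tailed Student t-test
(pooled variance; group sizes of 3–5 littermate pairs make the
equal-variance form the conventional default, Welch available by flag).
Zero-variance degenerate groups return p = 1 for equal means and p = 0
(reported as < 1e-6) otherwise, instead of NaN.  No multiple-testing
correction is applied.

## FISH co-localization

Inputs are physical micrometre coordinates (conversion from pixels uses the
configured xy pixel size and z-step, default 0.3 um per optical section).
A pair of signals interacts iff the Euclidean 3D center-to-center distance
is *strictly* below the threshold (default 1.0 um; a distance of exactly
1.0 um does not count).  Genotype frequencies are compared with Fisher's
exact test (two-sided) — the appropriate small-count exact test where the
upstream protocol names none; chi-square is available by flag.

## What the synthetic data emulates — and what it does not

The generators exist so that every stage has inputs with the statistical
structure the analysis assumes, with known truth:

* **4C**: cis weight `(1 + d/d0)^-alpha` (power-law decay with offset, the
  standard 3C contact model; defaults alpha = 1, d0 = 10 kb) with a uniform
  background floor equal to the trans weight, an inflated self-ligation
  weight on the bait, and planted contacts as multiplicative enrichments —
  so a planted multiplier of 20 is an exact 20-fold enrichment over local
  background both in cis (outside the decay zone) and in trans.
  Between-replicate overdispersion is Dirichlet-multinomial: per-fragment
  intensity `Gamma(w_i/phi, phi)` (variance-to-mean ratio phi, default
  0.01) then multinomial counts.  Reads are placed at distinct 5' positions
  within fragments so deduplication does not collapse simulated signal.
* **qPCR**: `Ct = -log_E(quantity) + N(0, sd)`; inverts exactly at zero
  noise.
* **FISH**: co-localized pairs at distance Uniform(0, t), others
  Uniform(t, 5t); the realized frequency equals the request by
  construction.

Not emulated: sequence-level read errors, barcodes and adapters, PCR
duplicates by sequence, mappability and GC structure of a real genome,
fragment-length biases of real digests, partial-digestion artifacts, and
image segmentation upstream of FISH centers.  Passing the recovery tests
therefore demonstrates that the *statistical pipeline* is correct and
calibrated under its own model assumptions — not that real mouse-brain
libraries would yield any particular interaction list.

### Scenario sizes

The shipped scenarios use one 6 Mb cis chromosome plus four 2.5 Mb trans
chromosomes at a 25 kb mean fragment size (~640 fragments, ~560 in the
unmasked universe), 2 replicates of 10^5 reads, and 30 cis + 20 trans
planted contacts at 20x background.  The universe size follows from a
power consideration: under the null, two independent top-q call sets
overlap in about `q^2 x |universe|` fragments, so a universe of ~560 keeps
the expected chance overlap (~0.06 fragments among non-planted sites after
the planted calls fill their slots) far below 10% of a 50-contact common
set, while the top-10% call budget (~56) still exceeds the 50 planted
contacts.  The background depth is chosen so essentially every fragment
receives at least one read and the interacting-site universe matches the
library.  Null-model calibration uses 50 independent seeds at 3 x 10^4
reads.  These sizes make the whole validation suite run in well under a
minute while leaving every assertion statistically sharp.

## Known limitations

* The estimator treats replicates independently; there is no hierarchical
  shrinkage across replicates and no per-fragment significance test — the
  calling rule is the rank threshold, as defined.
* Identity-mode intersection requires a shared fragment library; use
  proximity mode when comparing call sets from different digests.
* `elog2p` for zero-count fragments is prior-dominated and excluded from
  the calling universe; the estimates are still reported for completeness.
* The mean-fold/t-test summary of qPCR data ignores efficiency uncertainty
  from the standard curve.
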