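# Methods

## The inference problem

A monosomic chromosome in an IVF embryo biopsy is haploid and therefore
phased by default.  Given very low-coverage sequencing (on the order of
0.05x per homolog) of that monosomic embryo and of a disomic sibling from
the same IVF case, ldchase asks, region by region: does the disomic
sibling carry the monosomic sibling's haplotype?  Transitions between
"matched" and "unmatched" regions along the chromosome are meiotic
crossovers.  At such coverage almost no site is observed in both samples,
so the comparison leans on linkage disequilibrium (LD) in an external
phased reference panel: alleles observed on nearby reads are scored by
their joint (haplotype) frequency rather than independently.

## Likelihood models

For m reads from the monosomy (A-reads) and n reads from the disomy
(B-reads), with F the joint-frequency function estimated from the panel
(ancestry-weighted across populations for admixed samples):

* matched:    P_m = (1/2)^n * sum over subsets S of {1..n} of
  F(A_all u B_S) * F(B_Sc)
* unmatched:  P_u = F(A_all) * (1/2)^n * sum_S F(B_S) * F(B_Sc)

Each subset S is an assignment of B-reads to the homolog that may carry
the monosomic haplotype; reads on one homolog have their alleles scored
jointly, reads on different homologs independently.  The matched model is
the disomy model with one homolog's distribution replaced by
g(X) = F(A_1..A_m, X).  The log-likelihood ratio gamma = log(P_u/P_m) is
positive when evidence favors unmatched haplotypes.  For one read from
each sample this reduces to P_m = f(A,B)/2 + f(A)f(B)/2 and
P_u = f(A)f(B).

Recent admixture (parents from different populations) gives each disomy
homolog its own population distribution; the homolog potentially shared
with the monosomy uses the shared parent's population.  Distant admixture
replaces every frequency by the mixture sum_i alpha_i f_i.

Frequencies are exact counts over panel haplotype rows, computed as
AND-plus-popcount over per-(site, allele) row bitmasks so the 2^n subset
sums stay cheap (n up to 12 disomy reads, i.e. 6 per homolog).

### Zero frequencies

A finite panel assigns frequency zero to many real but unsampled allele
conjunctions, and sequencing errors create conjunctions that are
genuinely impossible; either would make one hypothesis exactly zero and
the LLR infinite.  When a joint frequency is zero but each constituent
allele is individually present, it is floored at (1/(2 N_hap))^2 —
strictly below any observable frequency (the smallest is 1/N_hap), so
unsampled conjunctions never compete with sampled ones, while the LLR
stays finite.  Flooring at the larger value 1/(2 N_hap) was tried and
rejected: it hands impossible conjunctions half the weight of a singleton
haplotype, which inflates the matched hypothesis enough to bias mean
gamma negative even on truly unmatched pairs.  If an observed allele is
absent from the panel altogether, both hypotheses are zero and the read
subsample is discarded as uninformative (the bootstrap redraws).

## Read prioritization

Reads are ranked by the haplotype diversity of the panel over their span:
enumerate the 2^k haplotypes over the k panel SNPs inside the read span
and count those with effective frequency strictly between f0 and 1 - f0
(default f0 = 0.05).  The score ignores the read's own alleles.  A
single-SNP read scores 2 when the minor allele frequency is at least f0,
otherwise 0.  Reads spanning more than 16 SNPs raise rather than
truncate.  The default informativeness threshold is score >= 1.

## Adaptive windows

Non-overlapping windows are grown left to right until they hold b
monosomy and 2b disomy informative reads (the disomy carries two
homologs).  A forming window is dismissed when consecutive informative
reads of one sample are more than 100 kbp apart (pairwise LD has largely
decayed by that distance) or when it reaches 350 kbp short of its quota;
scanning resumes at the read after the trigger.  The fraction of the
chromosome covered by emitted windows, C, doubles as a depth-and-library-
complexity score; reference candidates need C >= 0.5, ties broken to the
lexicographically smallest sample id.

The pipeline default is b = 6, which makes each window hold exactly one
full 6-read-per-homolog subsample and puts windows on the 10-100 kbp
haplotype scale at 0.05x coverage.  (b = 2 is the windows module's own
default floor; with the 6-read cap, b = 2 windows carry so few reads per
draw that per-window LLRs are nearly uninformative.)  Crossover
localization benchmarks use b = 10: per-window LLRs are stronger and less
variable, which sharpens the cumulative-sum extremum at the cost of
coarser windows — the right trade for changepoint mapping, where each
flank must span delta windows anyway.

## Bootstrap

Within each window, m = 100 subsamples are drawn without replacement —
up to 6 monosomy and up to 12 disomy reads, and always fewer than the
pool where possible (m-out-of-n resampling requires not exhausting the
pool, or every draw is identical).  Each draw's gamma is computed
exactly; the window summary is the mean and the Bessel-corrected variance
of the draws.  Note the variance is the dispersion of single-subsample
LLRs, not the standard error of the mean; it enters all downstream
confidence intervals as printed in the aggregation formulas.
Uninformative draws are redrawn, capped at 10m attempts before the window
is dropped.

## Bins and classification

Window means are aggregated over fixed bins (default 2 Mbp):
Gamma_bin = sum of window means, Var by the Bienayme formula, then
normalized by the window count g.  A bin whose confidence interval
gamma_bin +/- z*sqrt(Var(gamma_bin)) lies entirely above zero is
classified unmatched; entirely below, matched; otherwise ambiguous
(z = 1.96 by default).  Positive gamma means unmatched throughout — the
sign convention follows the definition of gamma, with the bin labels
inverted relative to an inconsistent prose passage in the source
derivation.

## Crossover detection

Crossovers are located on the cumulative track y_n = sum of window means,
v_n = sum of window variances.  The scan walks left to right and commits
alternating local extrema: a maximum at window j needs a left anchor i
(the lowest y since the previous call) with (y_j - y_i)/sqrt(v_j - v_i)
>= z and j - i >= delta, and a confirming k with a mirrored fall and
k - j >= delta (defaults z = 1.96, delta = 15 windows).  Anchoring the
flanks at the neighboring extremum — rather than searching all (i, k)
pairs — is what makes delta a guard on region size: alternating true
segments shorter than delta windows produce no calls.  kappa, the call
confidence, is the smaller of the two best admissible flank z-scores.

A maximum is an unmatched-to-matched transition, a minimum the reverse.
When the track makes a deeper same-type excursion after a committed call
(the intervening opposite extremum was too weak for z or too narrow for
delta), the deeper extremum is emitted as well and the skipped extremum
between the same-type pair is recovered as the interior window optimizing
the difference of the two flank z-scores; such calls are flagged
`recovered` and may fall below z.  Ties in any arg-extremum break to the
lowest index.

## Sibling attribution

All test embryos in a case are scanned against the same monosomic
reference, so a crossover on the reference chromosome reappears at nearly
the same position, with the same direction, in every sibling's callset.
The merged, sorted calls are scanned for same-direction clusters within a
region of l = 5 Mbp, first requiring all n embryos, then n-1, down to the
smallest majority (> n/2); within a candidate cluster an embryo
contributes only its call closest to the cluster mean, and overlapping
candidates resolve by larger size, then smaller span, then leftmost
position.  Cluster means become reference crossovers (with support
lambda = k/n and confidence min kappa over members); member calls are
subtracted from each embryo, and the remainder are the embryo's own
crossovers.  Calls of opposite direction never co-cluster: a reference
crossover flips every sibling's track the same way.

## Trisomy origin and landscape comparison

For trisomies, a per-region BPH/SPH z-score track (produced by a
trisomy-aware scan, which is an input here) is labeled BPH above +1.96
and SPH below -1.96.  Length-weighted fractions feed a decision tree:
>= 10% of the chromosome BPH is a meiotic error — MI if >= 50% of the
pericentromeric region is BPH, MII if >= 50% of it is SPH, else ambiguous
— otherwise >= 50% SPH is mitotic, else ambiguous.  The pericentromeric
region spans 20% of the chromosome length centered on the centromere
midpoint (clipped at the ends); acrocentric chromosomes use only the
q-arm side, 10% of the length from the centromere's distal edge.
Chromosomes need scan coverage C >= 0.5 to be classified.

Crossover landscapes are compared as eCDFs of pooled positions with a
two-sample Kolmogorov-Smirnov statistic; the p-value is computed by
permutation — exhaustive over all C(n1+n2, n1) assignments when that
count is manageable (default limit 200,000), otherwise seeded Monte
Carlo — counting assignments with D at least the observed value, observed
assignment included.

## Synthetic data

Benchmark panels are neutral coalescent simulations (msprime): effective
size 10^4, recombination and mutation rates 1.2e-8 per bp per generation.
At 500 haplotypes this yields about one biallelic SNP per 300 bp and LD
decaying over 10-100 kbp — the statistical features the method consumes.
Multi-population panels use demes splitting from a common ancestor 3000
generations ago, giving realistically diverged allele frequencies.  (An
earlier founder-mosaic generator was rejected: with allele draws
independent across founders its r^2 plateaus near 1/n_founders, far below
human short-range LD, and the likelihoods starve.)

Simulated samples are built from panel haplotype rows: a trio of parental
haplotype h1, offspring (h1, h2), and unrelated h3 from one population
(or h1, h2 from different populations for recent admixture).  Reads of
fixed length (default 75 bp, single-end) drop at uniform random midpoints
and copy the alleles of a per-read-drawn source haplotype — the parental
row for the monosomy, each offspring row with probability 1/2 for the
disomy.  Planted crossovers swap the row playing the shared homolog past
each breakpoint.  Family simulations give the reference chromosome its
own F1/F2 mosaic so a reference crossover flips every sibling's matching
state at once.  No sequencing-error, GC-bias, or amplification model is
included: passing benchmarks show recovery of planted signal under clean
reads with realistic sparsity and LD, not robustness to platform
artifacts.  Simulated trio haplotypes remain panel rows (so panel
frequencies are mildly favorable for them — the same situation as
benchmarking against a panel that contains the sample's relatives).

## Benchmark problem sizes and expectations

The acceptance script runs, per seed: bin classification (8 matched + 8
unmatched pairs, 6 Mbp chromosome, 2 Mbp bins), crossover localization
(100 single-breakpoint replicates, 10 Mbp chromosome, b = 10,
breakpoints placed in the central 38-62% band so both flanks can span
delta windows — crossovers nearer a chromosome end are undetectable by
construction), false-call control (10 matched-throughout pairs),
reference attribution (50 four-sibling families, 4.5 Mbp chromosome), and
mean per-bin balanced AUC at coverages 0.05/0.025/0.013x (6 + 6 pairs,
4 Mbp chromosome).  Localization is scored as the fraction of replicates
whose call falls in or adjacent to the true breakpoint's window; the
residual misses are argmin displacement of the noisy cumulative sum by
two or more windows, an irreducible feature of read sampling at this
coverage rather than a detector fault.

## Known limitations

* Windows, not base pairs, are the resolution quantum; at 0.05x and
  b = 10 a window is roughly 150-200 kbp.
* The per-window variance (the dispersion of subsample LLRs, not the
  standard error of their mean) makes downstream z-scores conservative
  rather than calibrated; thresholds were validated by simulation, not
  asymptotics.
* The simulator draws sample haplotypes from the reference panel itself
  and models no sequencing error.
* Distant admixture is supported at inference time (effective
  frequencies), but the simulator only generates non-admixed and
  recent-admixed samples.
* The BPH/SPH track consumed by the trisomy-origin classifier must be
  produced by an external trisomy-aware scan; only the downstream
  decision tree is implemented here.
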