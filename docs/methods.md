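# Methods

`pathsel` analyses a descendant-versus-ancestor (landrace versus wild)
contrast over the genes of a metabolic pathway: per-gene and per-codon
diversity statistics, NG86 Ka/Ks against an outgroup, a joint
empirical-percentile selection classifier, a flanking-gene sweep scan, a
maximum-likelihood multilocus HKA validation, and the pathway-position
rate-variation (PRV) correlation. Because resequencing panels of this kind
are not redistributable, the package ships a coalescent generator that
plants known selection regimes, and every downstream claim is validated
against that ground truth.

## Statistics

**Nucleotide diversity (θπ)** is the mean per-site pairwise difference.
Missing data (`N` and gaps, treated identically) are handled by *pairwise
deletion*: each pair (i, j) is compared over its own comparable sites L_ij
and contributes d_ij / L_ij. **Watterson's θW** is S / (a_n · L_eff) with
a_n = Σ_{i<n} 1/i, where S and L_eff come from *complete deletion* (sites
with no missing call), keeping the neutral sampling theory for S valid.
**Tajima's D** uses the 1989 normalising constants on raw counts
(complete-deletion Π and S). A subset with S = 0 has no D; it is carried
as a distinct `INVARIANT` marker and serialised as that literal, never as
0.0. **FST** is Hudson's 1 − Hw/Hb, with Hw the mean of the two
within-group π values and Hb the mean between-group pairwise difference;
Hb = 0 is defined as FST = 0, negative estimates are reported unclamped.
Codon-resolution tracks recompute π, FST and D in non-overlapping 3-bp
windows; the per-codon D is computed on the pooled two-population sample
(site-level statistics are conventionally reported across all lines), and
each polymorphic codon is classified synonymous / nonsynonymous (one
segregating site, by translation against the major codon) or complex (two
or more segregating sites, or a mid-CDS stop in the major haplotype).

**Ka/Ks** is Nei–Gojobori (1986) counting: per-codon synonymous site
fractions over the 9 single-base neighbours (changes to stop codons count
as nonsynonymous), path-averaged difference counts for multi-hit codons
(paths through stops excluded unless all are blocked), Jukes–Cantor
correction of both proportions, saturation (p ≥ 3/4) flagged rather than
extrapolated. The group sequence entering the comparison is the per-site
majority consensus (ties broken toward a reference allele, then
alphabetically); a mode averaging over all member×outgroup pairs exists
because which sequences enter such comparisons is a reporting convention,
not something the estimator dictates. Departure from neutrality (ratio = 1)
is tested by an exact binomial test of the integer (Na, Ns) split against
p0 = Sa/(Sa+Ss), with the doubled-tail two-sided convention (p = 2·min of
the tail probabilities, capped at 1). An NG86-style count-based estimator
was chosen over HKY-corrected variants because every piece of it is
enumerable and oracle-testable; at within-genus divergences (~0.1/site)
the extra corrections do not change sign or ordering conclusions.

## Selection classification

Gene-level calls use joint empirical-percentile criteria on the descendant
sample: *purifying* = θπ and θW below the 5th percentile of the empirical
background, FST above the 95th, and D < 0; *balancing* = θπ and θW above
the 75th percentile, D above the 95th, FST below the 90th. All
comparisons are strict, so boundary behaviour is deterministic; a
descendant sample with S = 0 is labelled `invariant` (D does not exist
there, so the purifying conjunction cannot be evaluated). The percentile
of a value is computed with one matching occurrence excluded from the
background and remaining ties counted half — the only reading under which
the minimum of a distinct background sits at percentile 0 and the centre
of a tied background at 50.

The background defaults to the analysed gene set but can be an external
table. This matters: outlier criteria presume a background that is mostly
neutral. When a third of the analysed set carries planted (or real)
selection, a "lower 5%" condition can only ever flag ~5 genes, so recovery
studies and the acceptance script rank genes against a separately
simulated neutral gene set, standing in for the genome-wide distribution
such criteria were designed around.

In recovery metrics, an `invariant` call counts as detection of a planted
purifying regime: complete fixation is the extreme of the diversity-loss
signature, and the sweep scan likewise reads fixation in a flanking gene
as sweep-consistent evidence (it raises the sweep flag together with any
other non-`none` label within ten genes either side, truncating at
chromosome ends).

Codon-level calls compare the populations directly: purifying where
(π_wild − π_landrace) exceeds a supplied genome-mean diversity with
FST > 0 and D < 0; balancing with the signs reversed. The genome mean is a
required input in principle; without one the pipeline substitutes the
analysed-set mean and logs it. A gene whose codon track shows both signals
gets the merged label `both`.

## Multilocus HKA

Each locus contributes two independent Poisson counts: segregating sites
S_i with mean k_i·θ_i·L_i·a_{n_i}, and fixed differences to the outgroup
D_i with mean θ_i·L_i·(T + c_i), where c_i = (n_i+1)/(2·a_{n_i}·n_i) is
the within-sample coalescent contribution to divergence (a documented
switch; on by default). Neutral loci have k_i ≡ 1; the selection model
frees k_i on the chosen loci, acting on polymorphism only. Maximisation
profiles θ̂_i (and k̂_i) in closed form at fixed T, leaving a 1-D
optimisation in T (coarse log-grid scan plus bounded Brent refinement —
deterministic, no gradients). The likelihood-ratio statistic
2(ℓ_sel − ℓ_neu) is non-negative by construction (the models nest;
sub-tolerance negatives are clipped) and referred to χ² with one degree of
freedom per selected locus. An empty selected set returns exactly 0. The
maximum-likelihood formulation replaces the original MCMC program while
keeping the same nested-model logic; calibration and power are verified by
parametric simulation from the model itself (the 34-neutral + 5-tested
locus design at θ·L·a_n = 30 per locus). Note the pipeline's HKA stage
builds counts from data in which descendant loci violate the
constant-size neutral model (they passed through a bottleneck), so its
per-gene p-values are comparative evidence, not calibrated tests.

## PRV and trees

Kendall's τ-b (tie-corrected — pathway positions are heavily tied) relates
the pathway pleiotropy index to Ka/Ks per pathway and group; p-values come
from exact permutation enumeration for n ≤ 8 (the tie structure is
permutation-invariant, so ranking |C − D| suffices) and from the
tie-adjusted normal approximation otherwise. The test excludes undefined
ratios, requires three usable genes, and repeats itself with the single
maximum-ratio gene dropped as a robustness check. Trees are UPGMA on
per-site p-distances with pairwise deletion (no multiple-hit correction —
within-species divergences are far from saturation); ties on the minimum
merge distance break toward the lexicographically smallest label pair, and
children are emitted in label order, so output is deterministic.

## The synthetic-data generator

The generator emulates the study conditions: two populations of 20
haplotypes each, ~100 coding genes of 0.5–5 kb across three pathway
variants with positions 1–6, ancestral per-site diversity θ = 0.001 (the
observed scale for such panels), an outgroup at 0.1 substitutions/site,
and purifying-dominated coding evolution (default ω = 0.2).

Genealogies come from a self-contained two-deme Hudson coalescent without
within-gene recombination. The wild deme has constant size 1 (in 2N
units). The landrace deme follows a domestication demography of
*bottleneck plus expansion*: a large recent epoch (relative size 50 back
to 0.8 × the split time of 0.05) and a severe brief bottleneck from there
to the split, whose size is solved analytically from the expected
pair-coalescence time so that the planted landrace/wild diversity ratio
(0.8 for neutral genes) holds in expectation. The expansion epoch is not
cosmetic: a bottleneck alone tilts the descendant site-frequency spectrum
toward intermediate frequencies (mean Tajima's D ≈ +0.5 in pilots), while
real domesticated panels show near-zero to negative mean D; without the
expansion, the balancing criterion's "D above the 95th percentile" is
unreachable because the neutral D tail absorbs it. Mutations are
infinite-sites Poisson at θ/2 per site per unit time.

Planted regimes modify the landrace side only:

* **purifying** — a recent hard sweep: the post-sweep recovery epoch is
  0.02 × the split time, so most genes are invariant or carry only young
  variants; the bottleneck size is solved for a diversity ratio of
  bottleneck × 0.05. Residual landrace-private variants with count ≥ 2 are
  resampled toward singletons with a geometric weight (p = 0.5), fixing
  the negative-D signature.
* **balancing** — an old balanced polymorphism: three haplotype classes at
  intermediate landrace frequency (0.4–0.6) and lower wild frequency
  (0.25–0.4), marked at enough linked sites to raise landrace diversity to
  bottleneck × 4; the within-class baseline is additionally bottlenecked
  (0.35 × the neutral ratio), reflecting that only the balanced classes
  escape the domestication squeeze. Sharing the classes with the wild
  sample is forced by arithmetic, not taste: a landrace-private
  intermediate-frequency class adds ~0.47 per site to Hb but only ~0.26 to
  Hw, driving Hudson's FST of every balanced gene into the top decile of
  the background and thereby failing the very criterion (FST below the
  90th percentile) that defines balancing candidates. The corollary is
  that wild diversity at balanced loci is also elevated — as it is at real
  balanced loci — so the planted contrast is against the neutral landrace
  level, not the same gene's wild sample.

One intermediate-frequency variant alone (the obvious minimal mechanism)
cannot produce a ×4 diversity change — a single site contributes at most
~0.5/L to per-site π — hence classes of linked marked sites.

The outgroup sequence evolves by accept–reject proposal: uniform
single-base proposals, synonymous changes accepted with min(1, 1/ω) and
nonsynonymous with min(1, ω), stop-creating proposals rejected, total
accepted count Poisson(divergence × L). Because NG86 site fractions equal
the proposal fractions, the realised dN/dS matches the planted ω, which is
what makes ω-recovery tests meaningful.

Every gene records truth (regime, realised per-group π, deme size, ω);
datasets are byte-identical under a fixed seed, with per-gene substreams
so single genes can be regenerated independently.

## What the generator does and does not emulate

It reproduces the moments the analysis consumes (diversity levels and
ratios, SFS skews, differentiation, divergence, dN/dS) but not: within-gene
recombination (whole-gene statistics are noisier than real data with
recombination, which mildly *understates* classifier performance on real
panels), sequencing or alignment error, missing data (the IO layer handles
`N`/gaps but simulated data are complete), codon-usage or CpG mutation
bias, gene flow between the populations, or linked selection across
neighbouring genes (sweep-scan clusters must be planted explicitly).
Passing recovery tests therefore demonstrates the statistical machinery is
correct and calibrated under the stated model — not that real panels meet
those assumptions.

## Problem sizes

Monte-Carlo checks in the test suite use the designs stated above: 1000
neutral genes (n = 40, θL = 3) for estimator calibration; a seeded
100-gene dataset (15 purifying × 0.05, 15 balancing × 4, 70 neutral) with
a 200-gene simulated neutral background for classifier recovery; 500 null
and 200 power replicates of the 39-locus HKA design; 100 replicates for
PRV power (ω ramp 0.1→0.8 over six positions, five genes each, L = 3 kb,
divergence 0.1) and for ω recovery. The acceptance script recomputes the
same quantities at moderately reduced replicate counts, chosen as the
smallest designs whose Monte-Carlo error is well inside the margins being
demonstrated.

## Known limitations

* The empirical-percentile criteria are outlier detectors: on a purely
  neutral input they still flag a small tail (bounded in tests at 10%).
  HKA validation is the second tier precisely because of this.
* NG86 with Jukes–Cantor correction is biased at high divergence; the
  saturation flag is a hard stop, not a fix.
* The HKA composite likelihood ignores linkage between S and D at a locus
  and between loci; its χ² reference is asymptotic in locus counts.
* Unphased heterozygous VCF input is rejected unless pseudo-phasing under
  a recorded seed is requested; the statistics are defined on haplotypes.
* With n = 20 haplotypes, per-codon Tajima's D takes few distinct values;
  codon-level calls should be read as screening annotations.
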