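# Methods

## Scope and model

`oncoclade` analyses a cohort of tumors characterized three ways: genome
wide copy-number aberrations (aCGH), microsatellite instability (a
5-marker mononucleotide panel), and promoter methylation of a 15-gene
candidate panel.  The unifying idea is cladistic: each copy-number
aberration is a derived character (state 1) relative to the normal genome
(state 0), so tumors can be grouped by shared derived aberrations under
maximum parsimony, and the cohort's summary statistics stratify by MSI
status.

## Copy-number calling

**Segmentation.**  Probe log2 ratios are smoothed by a moving average
over a fixed genomic window (default 0.2 Mb).  A probe is significant
when |smoothed mean| / σ̂ ≥ z (default z = 2.5), where σ̂ = 1.4826·MAD of
all of the sample's probe ratios — a plain SD would be inflated by the
aberrant segments themselves.  Maximal runs of significant probes with a
common sign become candidate intervals; same-sign runs separated by less
than one window width are merged, since a sub-window dip is below the
resolution the smoothing scale claims.  Run boundaries are then trimmed
back to probes whose raw ratio is at least half the run's median
magnitude: without trimming, the smoothing kernel smears every boundary
by half a window, and a noiselessly planted interval would not be
recovered exactly.  The interval's fold change is 2^(mean raw log-ratio).
A vendor pipeline would pair this z-score stage with a proprietary
second-stage algorithm (threshold 6.0); that stage is deliberately not
reimplemented, and the constant is kept in configuration for provenance
only.

**Fold filter.**  Calls are kept when fold > 1.2 (gain) or fold < 0.8
(loss).  The inequalities are strict — "above"/"below" read literally —
so boundary values 1.2 and 0.8 are dropped; both thresholds are
configurable.  These are deliberately sensitive thresholds meant to keep
any recorded aberration.

**Gene events and summaries.**  A gene-level event is emitted for every
(gene, interval) pair overlapping by ≥1 bp on the same chromosome
(0-based half-open coordinates everywhere), de-duplicated per
(sample, gene, direction).  Chromosome summaries count filtered
intervals — not probes — per chromosome, split into gains ("Amplif.")
and losses ("Del.") and by sex, with Total = Amplif. + Del. by
construction.  Whether the original tabulation counted intervals or
probe runs is not recoverable; this package counts filtered intervals.

## MSI classification

Samples with ≥2 unstable panel markers are MSI-H, exactly one unstable
marker MSI-L, none MSS.  Markers may be missing; when fewer than
`min_evaluable` (default 4 of 5) markers are evaluable, classification is
refused and an explicit `unclassifiable` status returned.  The default of
4 avoids calling MSS from sparse data while tolerating one failed PCR.

## Methylation tables

Methylated fraction per gene is computed over evaluable calls (NA
excluded gene-wise, as MSP panels report gene-wise), as a percentage to
one decimal under round-half-even.  Stratified associations use the
Pearson chi-square without Yates continuity correction — the convention
matching the default "Pearson Chi-Square" row of mainstream clinical
statistics software — with Fisher's exact test substituted (and flagged)
for 2×2 tables containing an expected cell below 1.  Tables with no
variation in methylation state yield p = NA with a reason.  MSI is
dichotomized as MSI-H vs the rest: MSI-L tumors behave like MSS tumors in
this assay context, and the stratified sample sizes of the reference
cohort (5 vs 22) only add up under that reading.

## Polarity assessment (binary character matrix)

All specimens' filtered aberrations are pooled and duplicates removed;
each specimen is scored 1/0 against the pooled list.  Character identity
defaults to the exact canonical interval plus direction; a merge
tolerance snaps coordinates to a grid so near-identical breakpoints can
merge, and a gene-level mode keys characters by (gene, direction)
instead.  Both identity modes are defensible — the aberration unit
(probe interval vs gene) underlying the original matrix construction is
not documented — so the chosen mode is recorded in output metadata.
All-zero characters are impossible by construction; all-one characters
(present in every specimen) are retained even though they are
parsimony-uninformative, because they belong to the pooled aberration
list.  Serialization is discrete-character PHYLIP (header `ntax nchar`,
names sanitized to 10 characters with a mapping table emitted when
truncation changes anything).

## Parsimony

**Character models.**  Wagner parsimony (free 0↔1 reversals, Fitch
counting) is the default; Camin-Sokal (irreversible 0→1) is available
for the reading in which an aberration, once acquired, never reverts.
Wagner is the default because it is the least-assumption model and the
conventional default of binary-parsimony programs.  Camin-Sokal length
of an unrooted tree is the minimum over root placements of the number of
0→1 transitions.

**Searches.**  Exhaustive enumeration covers ≤9 taxa (135 135 unrooted
topologies).  Branch-and-bound is exact: taxa are inserted in order, and
a partial tree is pruned when its length plus the number of characters
that are non-constant overall but still silent in the partial taxon set
exceeds the incumbent (lengths are non-decreasing under taxon insertion;
the silent-character count is a valid completion bound for both models —
for Camin-Sokal only all-zero-prefix characters are counted, because an
all-one prefix has already paid its single gain).  The heuristic does
stepwise addition under a random addition order followed by
nearest-neighbor-interchange hill climbing, with `n_starts` restarts; it
is deterministic given a seed and can never report a length better than
the exact optimum, since every tree it reports is scored by the same
Fitch counting.  Ties are first-class: all optimal trees are retained up
to a cap (default 1000, recorded when hit), and a strict consensus is
reported next to a deterministic exemplar, because a single-tree output
would overstate resolution.

**Rooting and node characters.**  The root is the aberration-free
genome: a hypothetical all-zero taxon is attached at the edge minimizing
total length (first edge on ties, in deterministic enumeration order),
the tree is rooted there and the pseudo-taxon removed.  Internal nodes
are numbered in preorder from the root; the numbering is recorded in the
output so node references are reproducible within a run (any numbering
produced by an external program's internals would not be recoverable).
Each node carries two defining-character lists: *strict* synapomorphies
(characters whose 1-state leaves are exactly the node's leaf set) and
*reconstructed* gains (characters whose state flips 0→1 on the node's
stem under a Fitch final pass with the ancestral state forced to 0).  On
conflict-free data the two coincide; under homoplasy the reconstructed
list depends on the reconstruction convention and is labeled as such.

## Cohort statistics

Group summaries are median and 25–75% interquantile under the
Hyndman–Fan type 6 rule: interpolate the sorted sample at rank
h = p·(n+1), clamped to [1, n].  This rule was fixed because every
interquartile printed in the reference cohort's summary tables (12.75,
105, 62.5, 31, 55, 54.75, 70.5, 6.5, 34, 16, …) is exactly reproduced by
it from the clinical table — the single most consequential
reverse-engineered convention in the package.  Values the source prints
with truncation rather than rounding (256 for 256.5, 713.7 for 713.75,
148 for 148.75, 54.7 for 54.75, 67 for 67.5) are documented as
formatting discrepancies and asserted at their exact type-6 values.
Categorical associations use the Pearson chi-square without continuity
correction.  For group comparisons of numeric variables both a
mean-based test (t-test / one-way ANOVA) and a rank-based test
(Mann–Whitney U / Kruskal–Wallis) are reported side by side and neither
is privileged: the reference tables print p-values (0.02, 0.006) without
naming the test that produced them, so no printed p is asserted against
a specific test.

## Synthetic cohorts

The generator reproduces the statistical skeleton the analysis assumes:

| parameter | default | rationale |
|---|---|---|
| MSI proportions (MSS, MSI-L, MSI-H) | 18/27, 4/27, 5/27 | reference cohort tally |
| aberration-count means by group | 37 / 256 / 10 | reference group medians |
| count dispersion (NB size) | 0.8 | per-tumor counts span 1–827; Poisson is far too narrow; dispersion is a modeling choice exposed in config |
| P(right-sided) by group | 1/18, 0, 0.8 | reference location split |
| p16 / MLH1 methylation (MSI-H vs rest) | 0.60, 0.80 vs 0.045 | reference stratified frequencies; remaining 13 genes likewise |
| chrX effect | 0.9 | X events amplified in males / deleted in females in most carriers |
| age means by group (years) | 63 / 40 / 57 (SD 12) | reference age medians |
| probe spacing | 25 kb | ~10^5 probes genome-wide scaled to the simplified genome |
| probe noise SD (log2) | 0.2 | typical aCGH per-probe scatter |
| interval lengths | 50–200 kb, grid-aligned | several probes per event; alignment makes exact recovery well-defined |

Intervals are placed uniformly over a simplified genome (22 autosomes +
X at 10 Mb, Y at 5 Mb — round lengths, no real coordinates), with
rejection of overlaps within a sample; planted clades are sets of
identical intervals injected into every member and excluded from
everyone else's background, so their characters are exclusive by
construction.  All randomness flows from one seed through per-sample
substreams; identical configs give identical cohorts.  The planted truth
(group labels, per-sample interval counts, clade characters) is a
separate sidecar file that no analysis stage reads.

What the generator does **not** emulate: tumor purity and ploidy, GC
waves and other probe-level artifacts, recurrent breakpoint hotspots,
real genome coordinates, and correlated aberrations beyond the planted
clades.  Passing tests therefore demonstrate the correctness and
statistical power of the algorithms under the planted model, not
performance on real arrays.

## Problem sizes used in the checks

The acceptance checks run: exact-search agreement on 100 seeded
7-taxon × 20-character matrices (branch-and-bound must match exhaustive
100/100, heuristic ≥95/100); perfect-phylogeny recovery on planted
conflict-free matrices of 8–15 taxa; planted-effect detection on 100
cohorts of n = 200 (MSI-H aberration deficit by Mann–Whitney, p16–MSI
association by chi-square, each at p < 0.05 in ≥95%); planted-clade
recovery in strict consensus on 100 cohorts of 15 samples with clades
sharing ≥5 exclusive aberrations (≥95%); segmentation recovery of a
1 Mb fold-1.5 interval at 10 kb spacing (noiseless: exact; noise 0.2:
≥50% reciprocal overlap in ≥95% of 200 replicates); and chi-square
type-I error within [0.03, 0.07] over 2000 null tables.  Clade recovery
uses 15-sample cohorts rather than 200-sample ones: tie-rich heuristic
search over hundreds of taxa is not informative about the consensus
machinery and the planted-clade property is size-invariant, while the
statistical power checks do use the full n = 200.

## Numerical and degenerate-input conventions

Quantiles of a single value return that value (rank clamping).  Empty
probe tracks yield no calls; a noiseless track has MAD 0, replaced by a
tiny epsilon so any non-zero smoothed mean is significant.  Contingency
tables drop empty rows/columns before testing and refuse degenerate
remainders.  Matrices require ≥3 specimens (no unrooted topology
otherwise).  Heuristic search ties are de-duplicated by bipartition
sets.  The branch-and-bound node budget (default 5·10^6 partial trees)
raises rather than silently truncating the search.

## Known limitations

* The vendor's second-stage segmentation algorithm is not implemented;
  recovery rates describe the z-score stage alone.
* Exact reproduction of any particular published cladogram topology is
  out of reach without the underlying per-sample aberration lists; the
  package reproduces the method, the in-cohort summary statistics, and
  recovery of planted structure.
* The heuristic search explores NNI neighborhoods only (no SPR/TBR) and
  no bootstrap support is computed.
* Gene panels ship with toy coordinates on the simplified genome; real
  genome-build coordinates are intentionally out of scope.
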