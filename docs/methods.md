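# Methods

## Domain model and position convention

A bZIP domain is modeled as three contiguous segments: a 16-residue basic
DNA-binding region, a 9-residue hinge, and a leucine-zipper coiled coil.
Domain positions are numbered without a zero: the basic region spans
−25..−10, the hinge −9..−1, and the zipper begins at +1. The invariant
asparagine sits at −18 and the invariant arginine/lysine at −10, which fixes
the anchor offsets used throughout: anchor + 8 is position −10 and
anchor + 18 is the first zipper residue. This is the only numbering under
which all the landmark positions used in the family literature (−18, −10,
hinge −5, basic −20, "nine residues upstream of R/K") are simultaneously
consistent, and −25..−10 is the unique 16-residue window ending at the
invariant R/K.

The scanner requires, at anchor `i`: `N` at `i`, `R`/`K` at `i+8` (`I` is
admitted under `--relaxed` to capture the isoleucine binding-site variant),
`L` at `i+18`, and at least `min_heptads` leucines (default 2) spaced seven
residues apart from `i+18`. `X` never satisfies a motif position. All hits
are reported in order; downstream stages use the first. Since nothing in the
sequence marks the zipper's C-terminal end, the zipper span is capped at
`max_heptads` (default 8) heptads or the sequence end, whichever comes
first; the cap is configurable and affects only how much C-terminal
sequence enters the dimerization statistics.

Binding-site classes are total over residue pairs: `canonical_R` = (N, R),
`variant_K` = (N, K), `variant_I` whenever −10 is isoleucine, otherwise
`noncanonical`.

## Intron phases and domain patterns

Gene models are lists of CDS exon intervals (1-based, inclusive) in
transcription order; GFF3 phase columns are ignored and recomputed from
exon lengths, keeping the mapping self-consistent. The coordinate map is a
bijection between genomic and CDS positions (minus-strand exons traversed
end-to-start), with residue *p* occupying CDS nucleotides 3p−2..3p.

An intron after `cds_offset` coding nucleotides has phase
`cds_offset mod 3`. Labeling rule: a P0 intron lying between codons *p* and
*p*+1 is labeled with the N-terminal residue *p*; P1/P2 introns carry the
residue whose codon they interrupt. This single rule reproduces both
standard descriptions of domain-window introns — "at −5, between Gln and
Ala" (P0) and "at −20 in phase 2".

Patterns are matched strictly on the multiset of (region, position, phase)
within −25..−1: *a* = {(hinge, −5, P0)}; *b* = two P0 introns, one basic
one hinge; *c* = {(basic, −20, P2)}; *d* = empty. Everything else is
`other` rather than being forced into the nearest class, so real data that
violates the four-pattern regularity is surfaced, not hidden.

## Heptad register and dimerization statistics

The register anchors the first zipper leucine (+1) at slot *d* of heptad 1
and continues cyclically (e, f, g, a, b, c, d, …), leaving heptad 1's a–c
slots absent and allowing a trailing partial heptad. The anchor slot is
configurable (`register_offset`) because the field's numbering of heptad 1
is not standardized; when reproducing numbers from a published heptad
alignment, ingest that alignment directly (`read_register_table`) and its
register is taken as authoritative.

Interface composition at a/d/e/g is residue-pooled over all heptads of all
registers (`X` excluded from denominators). An alternative reading of
family-wide percentages — counting proteins rather than residues — is
deliberately not the default; the pooled convention is documented here and
the per-heptad denominators are always reported alongside.

g↔e′ pairs couple g of heptad *n* with e of heptad *n*+1 of the same
sequence, the self-pairing proxy for a parallel homodimer that single-
sequence surveys use. Categories depend only on membership in
basic = {R, K} and acidic = {D, E}; histidine is treated as uncharged.
Per-heptad frequencies divide by the pairs observed at that heptad index
(default); a pooled-denominator variant is available (`per_heptad=False`).

## Ka/Ks

The estimator is Nei–Gojobori (1986) with equal pathway weights. Per-codon
synonymous site counts are the fraction of the three single-base changes at
each position that preserve the amino acid; changes to stop codons count as
nonsynonymous, which keeps S + N exactly 3 per codon. Site counts are
averaged over the two sequences. Codons differing at two or three positions
average Sd/Nd over all substitution orderings, skipping orderings that pass
through a stop codon (under the standard code every sense-codon pair retains
at least one stop-free ordering; a fallback averaging over all orderings
exists for completeness). Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)·p); p ≥ 3/4 is reported as saturated (NaN, flagged).
Ka/Ks is undefined (None) when Ks is zero or saturated.

This deliberately replaces the YN-style maximum-likelihood estimators used
by off-the-shelf calculators: the downstream uses here (a 0.5 purifying-
selection threshold and binned Ks histograms) do not require
transition/transversion or codon-frequency corrections, and NG86 admits an
exact enumeration oracle that the test suite exploits (agreement to 1e−12
over all 61×61 sense-codon pairs). Consequently Ks values are not expected
to match ML estimates on real, biased sequence data to better than the
usual NG-vs-YN discrepancy.

The purifying-selection summary partitions defined ratios at a strict
`ratio < cutoff` (default 0.5). Ks histograms use half-open bins
[k·w, (k+1)·w) with w = 0.05 by default; the global peak takes the lowest
maximal bin, and a simple strict local-maximum scan locates secondary modes.

## Tandem clusters

Gene order per chromosome plus undirected similarity edges; membership
requires e-value strictly below 1e−20. Clusters grow greedily left to
right: the next gene joins if it is similar to at least one current member
and lies at most one position beyond the last member (one unrelated gene
tolerated per gap). A `per_cluster_tolerance` flag restricts the skip
budget to one per cluster in total. Clusters never span chromosomes, only
maximal clusters are emitted, and the result is invariant to edge order.

## Expression profiles and 2^−ΔΔCt

Profile classification of (DAF20, DAF40, DAF60), checked in order with an
FPKM floor (default 1.0) and fold threshold (default 2.0):
`not_expressed` if all three are below the floor; `I` if DAF20 ≥
fold·max(DAF40, DAF60); `II` if DAF40 ≥ fold·max(DAF20, DAF60); `III` if
fold·DAF40 ≤ min(DAF20, DAF60); else `IV`. The verbal group descriptions in
family surveys ("up-regulated early", "highly expressed throughout") do not
pin down thresholds, so this operationalization keeps both knobs explicit
and configurable, and the label is invariant to uniform rescaling above the
floor.

qPCR: per replicate ΔCt = Ct(target) − Ct(internal control gene);
ΔΔCt = mean ΔCt(treatment) − mean ΔCt(reference); fold = 2^−ΔΔCt. The SE is
taken over per-replicate treatment folds normalized to the reference mean.
Significance uses a two-sided t test on the ΔCt values — not on folds,
since ΔCt is the approximately normal scale — Student's (equal-variance) by
default to match the conventional naming, Welch by flag. DE counts per time
point use raw p < α with no multiple-testing correction by default
(matching common qPCR practice); Benjamini–Hochberg is available by flag.

## Synthetic-data generator

The generator is first-class, tested code and defines the conditions under
which the pipeline is validated:

- **Proteins**: flank + basic(16) + hinge(9) + heptads, with the invariant
  residues planted at −18/−10. Flanks and randomized non-landmark residues
  are drawn from the amino-acid alphabet *without* asparagine, so the
  planted anchor is the only possible motif match and recovery can be
  asserted at 100%. The default hinge places Gln at −5 and Ala at −4, the
  junction split by pattern-*a* introns.
- **Gene models**: reverse translation with a seeded uniform codon choice
  (codon identity only matters where `evolve_pair` controls it), CDS split
  at planted positions/phases, random introns of 60–200 nt with fixed
  GT..AG ends (phase arithmetic depends only on exon lengths), both
  strands. The exon-concatenated CDS retranslates to the input protein by
  construction.
- **Codon pairs**: substitution events are proposed per site at a Poisson
  rate equal to max(dS, dN), uniform over the three alternative bases (the
  Jukes–Cantor geometry the estimator assumes), accepted with probability
  dS/max or dN/max according to whether the change is synonymous on the
  current background; events creating stops are discarded. Realized
  divergence therefore matches the targets in expectation with genuine
  multiple hits. At high divergence (dS ≈ 0.9) the estimate runs a few
  percent high because two-fold-degenerate sites saturate at p = 1/2 while
  the JC correction assumes 3/4; this bias is inherent to NG86+JC, not to
  the simulator.
- **Gene order tables**: within-cluster e-values drawn below 1e−21,
  background edges at or above 1e−20, so the threshold is exercised on both
  sides.
- **Expression**: planted group patterns at a configurable fold (default 5)
  with mean-one multiplicative log-normal noise of configured CV (default
  0.1), the simplest positive noise for count-derived abundances; default
  group sizes 24/37/15/17/22. Ct tables carry three replicates per
  condition, Gaussian technical noise, and the internal control gene.

What the generator does **not** emulate: genomic background (transposons,
pseudo-genes, paralog families that share motif context), alternative
splicing, codon-usage bias and transition/transversion bias, FPKM
mean–variance structure of real RNA-seq, or PCR efficiency differences
between primers. Passing the recovery suites therefore demonstrates the
correctness of the computations under their stated models, not robustness
to every artifact of real data.

## Problem sizes and numerical choices

The test and acceptance runs use 1000 planted proteins, 500 gene models,
10 × 10,000-codon pairs per divergence target, 200 random gene-order
tables, and 1200 null qPCR genes — sizes at which sampling error is small
relative to the asserted tolerances while the whole suite stays fast.
Percentages are computed on exact integer counts; composition frequencies
are checked to 1e−9; NG86 agreement with its enumeration oracle to 1e−12;
divergence recovery to ±10% (dS = 0.3) and ±15% (dS = 0.9 and Ka). Ties in
histogram peaks break toward the lower bin. Degenerate inputs (empty
zippers, single-exon genes, fewer than two heptads or replicates,
non-codon-length CDS, internal stops, overlapping exons) raise or return
empty results explicitly rather than being coerced.

## Known limitations

- Real-proteome scanning (HMM profiles, BLAST homology) is out of scope;
  the motif scanner assumes the invariant signature is intact and will miss
  genuinely degenerate domains beyond the Ile variant.
- Codon alignment of real duplicate pairs (with indels) must come from an
  external aligner; the built-in helper only validates gap-free pairs.
- Collinearity/WGD block detection is not implemented; duplicated pairs are
  ingested as precomputed lists.
- Genome-scale quantities from real surveys (family sizes, genome-wide Ks
  peak positions, DE gene counts) depend on the genomes and RNA-seq they
  were measured on and are not reproduced by the synthetic conditions here.
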