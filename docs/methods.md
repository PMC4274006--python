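# Methods

`snptyper` re-creates, as testable code, the desk side of a Sanger-based
SNP-typing study of medicinal-plant landraces: three congeneric *Amomum*
species, a handful of DNA barcode loci, and the question of how many
landraces a given locus combination can tell apart. Because the study's
raw chromatograms and the proprietary typing software are not
reproducible at desk scale, the pipeline is exercised on a synthetic
panel whose statistical structure matches the study design, plus the
published per-combination SNP/ST count table, which is used as direct
input where the published numbers themselves are the data.

## Synthetic panel generator

The generator (`snptyper.synth`) emulates a 29-sample panel: 21 samples
of a focal species (A), 2 of a close variety-level neighbour (B), and 6
of a distant congener (C). Default loci mirror the study's trimmed
alignment lengths — ITS 660 bp, LSU D1–D3 714 bp, rbcL 568 bp, matK
818 bp — with planted substitution SNP columns (19, 11, 4, 1; 35 in
total), plus a 715 bp trnH-psbA-like locus with no SNPs and a
12-base mononucleotide run that interrupts sequencing.

Reference sequences are i.i.d. uniform over {A,C,G,T}; no attempt is
made to model real base composition, codon structure or indels (the
study reports substitutions only). Planted columns are partitioned
into roles:

* ~50% are fixed differences in species C (distant congener); up to
  five of those also carry a third allele in species B, so they
  separate all three species. These proportions follow the study's
  observation that roughly half its SNPs discriminated the distant
  species and five ITS sites separated all three.
* The rest is within-species variation, split between A and C in
  proportion to their sample counts. Each species keeps a founder
  block of identical samples (the species' core profile); every other
  sample is a single-SNP variant of the founder, one variation column
  per variant. Every third variant is planted as a heterozygote
  (ref/alt IUPAC code) rather than a homozygous substitution,
  reflecting the paralog-derived mixed bases the ribosomal loci show
  in practice.

This deterministic allocation makes the founder the hub of the minimum
spanning tree and yields two multi-ST groups under a ≤2-SNP rule (the
A radiation and the C cluster) with the B genotype ungrouped — the
qualitative structure the study reports. With the default counts the
panel has 20 STs among 29 samples; the generator's rule does not chase
the study's exact, data-dependent ST multiplicities (19 STs), which
are emulated structurally, not numerically.

### Trace model

Reads span the whole locus in both directions, for a configurable
number of individuals per sample (default 2, i.e. 4 traces per
sample×locus, 116 per locus over 29 samples). Quality values are flat
at `peak_qv` (default 55) to position 500, then decay linearly at
0.05 QV/base, plus optional Gaussian noise, clipped to [0, 60]; the
defaults keep noiseless traces comfortably above every QC threshold so
that failures are attributable to the planted failure modes. At a
heterozygous position the two strands basecall the two different
alleles as primary peaks, each with secondary-peak fraction
`het_secondary_fraction` (default 0.6 — above the 40% calling rule so
planted heterozygotes are recoverable); homozygous positions carry
|N(0, 0.02)| secondary noise. Since FASTQ has no channel for
secondary-peak fractions, each read is written with a
`<read_id>.sec.tsv` sidecar; no chromatogram (AB1/SCF) parsing is
attempted — the sidecar *is* the trace abstraction.

On the repeat-failure locus, a read collapses (QV ≈ 8) with
probability `failure_fraction` (default 0.655, chosen to emulate the
~34.5% success the study reports for trnH-psbA). The collapse covers
reference positions downstream of the repeat run, mapped into the
read's orientation, so both directions of an affected template retain
fewer than 200 clean bases; with the run starting at position 120 this
makes an affected read fail the CRL rule regardless of direction. A
synthesis-direction-only collapse was considered and rejected: with a
single run near one end, reverse reads would almost always pass, and a
"failure fraction 1.0" could never produce a 0% success rate.

## Trace quality control

Following the capillary-QC conventions the study used:

* **TS (trace score)** — mean basecall QV of the post-trim read;
  quality levels low/medium/high at 0–20 / 21–34 / 35–100.
* **CRL (contiguous read length)** — longest run of positions whose
  window-smoothed QV exceeds 20 (centred 20 bp moving average,
  shrinking at the ends). The phrase "window size of 20 bp" is
  ambiguous between per-base and windowed readings; the smoothed
  variant is the default because it matches the vendor tool's intent
  and is robust to single-base dips, and the raw per-base variant is
  available behind `smoothed=False`.
* **Pass rule** — TS ≥ 35 and CRL ≥ 200 bp; success rates are printed
  to one decimal, round-half-up (so 112/116 → 96.6).
* **End trimming** — from each end, advance inward until the terminal
  25-base window holds fewer than 3 bases that are low-quality
  (QV < 25) or ambiguous; 5′ first, then 3′ on the remainder. A
  shrunken terminal window is held to `min(max_bad, span)` so an
  all-bad tail can never qualify; without that cap an entirely
  low-quality read would keep its last two bases. Trimming is
  idempotent.

## Assembly and heterozygote calling

One forward and one reverse trimmed read per individual are merged by
the best ungapped offset alignment (no indels are simulated, and the
study's loci aligned gap-free). All offsets whose overlap reaches 80%
of the shorter read are scored; the one with the highest IUPAC-aware
match fraction wins (ties: longer overlap, then smaller offset) and
must reach 98% matches. "80% of the shorter read" resolves the
unnamed denominator in the published criterion. A two-base IUPAC code
is called only with secondary peaks above 40% on *both* strands and a
consistent allele pair — bidirectional confirmation — so positions
covered by a single strand can never be heterozygous; primary-base
conflicts without het evidence resolve to the higher-QV strand and are
flagged. Independently assembled individuals of the same sample must
agree; disagreement positions are flagged rather than averaged.

## SNP calling and ST assignment

SNPs are positions where a sample consensus differs from the
designated reference individual's sequence (the first founder-block
sample, playing the role of the study's authoritative specimen), in
1-based reference coordinates. IUPAC codes are categorical alleles:
A vs R is one SNP and a distinct genotype state. Alignments requiring
internal gaps are refused (flagged unalignable) rather than silently
calling indels. The allele vector over the SNP columns of a locus
combination (locus order, then position) is the sample's SNP genotype;
distinct vectors get ST numbers by first occurrence. Only the
partition is meaningful — the study's ST1–19 labels are
figure-specific. Samples missing any locus of a combination are
excluded from it, which is how the study handled its failing locus.
Discriminatory power per combination is reported as SNP and ST counts;
the Pearson correlation between them uses the standard product-moment
estimate with the two-tailed p from the t transform (n−2 df).

## Trees

* **UPGMA** on pairwise Hamming distances between profiles (the study
  clusters on "pairwise similarity", which orders pairs identically).
  Merge heights are d/2 so cophenetic distances come back in SNP
  units; ties merge the lowest-index pair. The cophenetic correlation
  measures clustering fidelity; ultrametric inputs give exactly 1.
* **Maximum parsimony** with Fitch small parsimony over categorical
  symbols. Search is exhaustive up to 9 taxa, otherwise NNI simulated
  annealing from a greedy random-addition start with geometric cooling
  (T0 = 5.0, ×0.95 per level, 100 proposals per level, stop below
  0.01 — the published tool's schedule is proprietary, so these are
  package defaults exposed in configuration). The tree is rooted on
  the longest edge of the longest change-count-weighted path, a
  midpoint-style reading of "deepest branch by maximum branch length".
* **Bootstrap** resamples SNP columns (the characters the tree is
  built from) with replacement and re-runs the annealing search per
  replicate; support is the percentage of replicates containing each
  reference bipartition. The library default is 1000 replicates; the
  pipeline configuration defaults to 100 replicates with a lighter
  schedule (T0 = 1.0, ×0.9, 20 proposals), which keeps a full run
  under a minute while leaving strong splits at or near 100%.

## Minimum spanning tree and groups

STs with zero distance collapse into nodes sized by membership. The
MST is grown Prim-style; among tied minimum-weight candidate edges the
already-included endpoint with the highest priority score —
10000 × (single-SNP variants) + 10 × (double-SNP variants), counted on
the full matrix — wins, then the larger node, then the lowest ST id.
Whether the published algorithm scores the attaching or attached end
of a tied edge is unstated; scoring the included endpoint is this
package's documented, configurable choice. The rule only resolves
ties — total weight always equals the unconstrained minimum, which the
tests verify against exhaustive spanning-tree enumeration. Groups are
connected components over MST edges of weight ≤ 2 with at least 2 STs;
founder candidates are ranked by single-SNP MST neighbours, then node
size, following the argument by which the study nominated its central
genotype as the ancestor.

## Determinism and problem sizes

A master seed derives per-stage seeds by CRC32 of the stage name, so
stages are independently re-runnable and two equal-seed runs produce
byte-identical artifacts (hash-checked in the manifest). Test and
script problem sizes: the default 29-sample panel everywhere the study
scale matters; ≤ 8 nodes where spanning trees are enumerated
exhaustively; 6–8 taxa where parsimony is checked against brute-force
state enumeration; 200 random reads for the QC window oracles; 100–200
bootstrap replicates in pipeline runs.

## What passing tests do and do not show

The generator reproduces the study's *design* (sample sizes, locus
lengths, SNP counts, failure modes, heterozygote visibility), not its
data: real chromatogram noise is not i.i.d., real loci have base
composition and alignment artifacts, and real heterozygotes can be
strand-biased. Passing tests therefore demonstrate that the
implementation performs the published procedure correctly on data with
the assumed structure — they say nothing about wet-lab recoverability,
and the biological interpretation of groups and founders is outside
the package's scope.
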