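# Methods

This note records the models, conventions and numerical choices behind
`tetracer`, and what the synthetic-data experiments do and do not show.

## Coordinates and alphabets

All internal coordinates are 0-based, half-open, plus-strand. Biological
TSS-relative promoter positions (−1 = base upstream of the start, +1 = the
start base, no position 0) are converted by `seq_core.tss_to_offset` given
the TSS index. Sequences are upper-cased on input and restricted to the
IUPAC DNA alphabet; `U` is rejected so RNA files fail loudly rather than
silently complementing wrongly.

## Element annotation

* **TIR search** is anchored at the element termini: candidate lengths are
  scanned from long to short and the first prefix whose reverse complement
  matches the suffix within `max_mismatch` substitutions wins. No interior
  offset scan is attempted — a TIR is terminal by definition, and
  `refine_element_boundaries` handles the one systematic offset that
  arises in practice: an alignment-derived indel region contains the
  duplicated target site on one side of the true element, so inward trims
  of up to 20 bp at each end are scanned for the longest exposed TIR
  (ties broken toward the smallest trim). Pipelines tolerate a few TIR
  mismatches (default 4 of 27) because the promoter copy of an old
  insertion has accumulated substitutions in its TIRs.
* **TSD search** is exact-match only by default (the diagnostic
  duplication is created perfectly at integration time); the longest
  k in [2, 20] with identical flanks wins, and no partial credit is given.
* **Consensus building** follows a majority rule with the gap fraction and
  base frequencies both computed over all rows: a column whose gap
  fraction reaches the threshold (default 0.5) is dropped; otherwise the
  single base at/above threshold is emitted, ties emit the minimal IUPAC
  code covering the tied bases, and columns where no base reaches the
  threshold emit the code of all bases present. Ambiguity codes are
  excluded pairwise downstream (K2P counting), so ties cost information
  rather than injecting noise.
* **ORF screening**: the longest ATG-to-stop reading frame over all six
  frames, in codons counting the ATG and excluding the stop; unterminated
  reading frames do not count. The non-autonomous call requires the
  longest ORF to stay below 100 codons — the sources this models state
  only "no open reading frame", and 100 codons cleanly separates absent
  coding capacity from the incidental micro-ORFs any kilobase-scale
  sequence contains.
* **Classification** is a pure decision table: TIR+TSD with no long ORF →
  non-autonomous class II; TIR+TSD with a long ORF → autonomous class II;
  no TIR but a terminal poly-A (≥ 8 A, either strand) → class-I-like;
  otherwise unclassified. The `YARNG` terminal-motif match is reported but
  never changes the class.

## Homology search and copy counting

Exact `word_size`-mers (default 11) seed candidate regions; seeds are
grouped when their diagonals differ by ≤ 100 (indel drift within one
alignment) and their subject positions by ≤ the query length, with a
sparse-cluster filter (≥ qlen/300 seeds) playing the role of BLAST's
two-hit heuristic. Each candidate region is then aligned with an optimal
local (Smith–Waterman, affine-gap, numba-compiled) dynamic program on a
window padded by the unseeded remainder of the query plus `x_drop`. This
replaces greedy x-drop extension deliberately: on desk-scale subjects the
optimal DP is affordable and guarantees that the best hit attains the true
local optimum for the scoring scheme (+1/−2, gap open −5, extend −2, a gap
of length L costing open + L·extend) — a property the tests verify against
an independent implementation. Copy counting keeps hits with identity and
coverage at or above the thresholds (default ≥ 0.85/0.85; a strict-> mode
exists) and collapses overlapping passing hits to the best-scoring one, so
nested or fragmented copies count once.

## Motif scanning and p-values

Log-odds are natural-log: `ln((c+α_b)/(Σc+Σα)) − ln(bg_b)` with the
per-column pseudocount defaulting to `max(0.01·column_total, 0.5)` split
in proportion to the background. The p-value of a score is the exact tail
probability of the column-sum distribution under the (default uniform)
background. For widths ≤ 10 the convolution runs on exact float sums with
the same left-to-right summation order used to score a site, so the DP is
bit-identical to full enumeration without enumerating; wider matrices use
an integer lattice of spacing 1e-3 log-units, with worst-case score error
bounded by grid·width (≈ 0.015 log-units at width 15, far below the
spacing of adjacent site scores in practice). A fixed-grid-only DP was
rejected because rounding can reorder outcomes that carry probability
mass ≥ 4⁻ʷ, which is incompatible with exact-agreement checks at small
widths. Overlapping hits are all reported; windows containing non-ACGT
characters are skipped. Expected background hit counts use
`E = (L − w + 1) · Pr(S ≥ t) · (2 if both strands)`.

## Distances, trees and dating

* **K2P**: pairwise deletion removes columns with a gap or ambiguity code
  in either sequence; transitions are A↔G and C↔T. The standard error is
  Kimura's analytic delta-method variance, not a bootstrap; simulations in
  the test suite confirm the empirical estimator SD matches it within 10%
  at the divergences of interest (d ≤ 0.1).
* **Neighbor joining** is the Saitou–Nei algorithm with deterministic
  tie-breaking (smallest active-node index pair) and negative branch
  lengths clamped to zero with the deficit moved to the sibling branch of
  the same join. NJ is exact on additive matrices, which the tests use as
  the primary oracle (plus a topology cross-check against scikit-bio).
* **Linearization** roots the tree on the outgroup's pendant edge at the
  point balancing the outgroup tip against the mean ingroup tip depth,
  then sets every internal node's height to the tip-count-weighted mean of
  its node-to-tip path lengths, clamps children to their parents, and
  scales ages so the calibration node (the MRCA of a given label set) sits
  at the calibration age. This tip-averaging scheme is a deliberate
  simplification of the full ordinary-least-squares linearization; on
  clock-simulated trees the recovered node ages sit within simulation
  noise of the truth (tested), which is the regime the pipeline targets.
* **Insertion dating** converts the element-vs-consensus distance with
  `t = d/rate` — single-lineage divergence, not `2rt`, because the family
  consensus approximates the element at the moment of insertion and
  divergence accrues on one lineage only. The interval is `(d ± z·se)/rate`
  with z = 2 by default, clipped at 0. The verdict against a reference
  node compares the whole interval with the node's age; because both ages
  share the calibration rate, the verdict is invariant under rescaling the
  calibration age (tested).

## Synthetic data: what it emulates, and what it does not

The generators draw uniform-composition random backbones (a GC knob
exists), evolve sequences under K2P with independent sites and a ts:tv
ratio of 2:1 (P = 2Q) — the divergence-vs-SE examples are insensitive to
this split at small d — and plant structural features with exact truth:

* element copies are inserted with genuine target-site duplications (the
  host k-mer at the integration point is duplicated), with placements
  screened so the duplication can neither extend nor truncate;
* synthetic elements carry exact TIRs, and interior ORFs above 50 codons
  are disrupted with stop codons, because the object being emulated — a
  non-autonomous element — genuinely has none;
* the duplication scenario grafts a gene duplication onto the species-tree
  stem of the ingroup crown: below the duplication node both paralog
  clades mirror the species topology, the element family consensus is
  instantiated on the Y-paralog lineage at the insertion age, and the
  promoter-borne copy then evolves at the clock rate. Coding alignments
  embed the neutral sites as third codon positions with invariant first
  and second positions.

Default scenario conditions are the emulated history itself: duplication
10 MY, insertion 8 MY, outermost calibration split 95 MY, clock rate
0.004 substitutions/site/MY (the rate implied by a divergence of 0.034
dating to ≈ 8.5 MY). The element length (12 kb) and neutral alignment
length (24 kb of third positions, i.e. a multi-gene concatenation) were
fixed by an a-priori power analysis: with z = 2 the dating interval is
then ≈ ±0.9 MY wide, narrow enough to resolve the 2-MY gap between
insertion and duplication; shorter sequences give intervals that straddle
the duplication node, which is a property of the data, not of the method.
A pilot simulation on seeds disjoint from the test suite confirmed the
design before the defaults were frozen.

What passing these tests does **not** show about real data: the generators
have no indel evolution within elements, no rate heterogeneity across
sites or lineages (in particular not the elevated post-duplication rate
real Y-linked duplicates can show, which biases duplication-age estimates
and is reported but not corrected here), no GC-content structure, and no
fragmented or nested old copies beyond the single engineered split. Copy
counts in a real assembly also depend on assembly quality in repetitive
regions, which no simulation here models.

## Pipeline conventions

The pipeline selects as the candidate element the Y-carried indel region
with the most genomic copies, refines its boundaries as above, builds the
family consensus by reference-anchored alignment (each genomic copy
globally aligned to the candidate and projected onto its columns — chosen
over an external multiple aligner to keep the chain self-contained and
deterministic), and dates the insertion against the configured reference
node. Promoter-pair region labels use Roman numerals from the TSS-proximal
(3′) end. Reports echo the effective configuration, and two runs with the
same config and seed produce byte-identical JSON (tested). Global promoter
alignment uses Bio.Align.PairwiseAligner (affine, +1/−1, gap open −4,
extend −0.5 in the open + L·extend convention); its first optimal
traceback is taken, which is deterministic across runs.

## Known limitations

* The TIR-length report can exceed the planted length by a few bases when
  mismatches are tolerated (a longer window with ≤ max_mismatch errors can
  subsume the true TIR); exact-match detection does not have this issue.
* `loss_from_other` calls rest on copy number alone; no outgroup synteny
  is consulted.
* Repeat-boundary refinement only trims (≤ 20 bp); grossly mis-segmented
  regions are not re-discovered.
* The homology module indexes subjects in memory and is intended for
  desk-scale genomes (≤ ~10 Mb), not assemblies.
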