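# Methods

## The curation model

`gapmend` treats reference curation as a set of *replacement edits* decided
by gene-anchored comparison against donor assemblies. The underlying
assumptions are:

* The reference annotation is trustworthy enough that gene bodies can serve
  as unique markers. Anchoring never uses exon structure — only gene-body
  intervals — so annotation detail does not matter, but gene *uniqueness*
  does: duplicated genes are excluded as anchors outright rather than
  disambiguated.
* Donor assemblies are collinear with the reference at the scale of a
  gap's flanking-gene pair. Local inversions are tolerated (a fully
  inverted donor region is used in reverse complement); rearrangements that
  split the two anchors across donor sequences or reorder them are treated
  as evidence against the candidate (`split_anchor`, `order_conflict`), not
  as something to resolve.
* Replacing gene-boundary-to-gene-boundary spans is safer than surgical
  N-run excision: the replaced span is delimited by sequence that can be
  independently validated (the flank check), whereas the bases immediately
  at an N-run's edge are exactly the bases an assembler was least sure of.
  Within-gene gaps replace the whole gene body for the same reason. The
  price is that closure sizes can greatly exceed gap sizes (a 25 bp
  placeholder gap can legitimately trigger a multi-hundred-kb gene-body
  replacement), which the edit ledger makes explicit.

## The anchoring aligner

The built-in aligner is an exact-k-mer seed-and-chain mapper over a
sorted-array index of every target k-mer.

* **k = 21** (2-bit packed): long enough that random 21-mer collisions in a
  sub-gigabase genome are negligible, short enough that ~1% point
  divergence leaves dense surviving seeds.
* **Repeat masking, `max_occ` = 50:** query k-mers with more than 50 target
  occurrences contribute no seeds. Masked query bases that fall *inside* a
  chained span are counted as aligned for coverage purposes (they are
  bridged by collinear unique anchors on both sides) but never contribute
  to identity.
* **Chaining:** longest strictly-increasing subsequence on (query, target)
  positions per strand; secondary chains at disjoint target loci are
  reported (up to 5), which is how duplicated anchors are recognized.
* **Scores:** coverage = chained-seed-covered bases / non-N query length.
  Identity is estimated as 1 − (coverage breaks / chained span), a break
  being a gap > k between consecutive chained seeds: an isolated
  substitution kills k overlapping seeds but produces exactly one break, so
  the estimate tracks true identity well below ~3% divergence and collapses
  above it — which is the desired behavior for an anchor filter meant to
  reject paralogs, not a general-purpose aligner.

The aligner is a contract (query → scored, strand-aware target hits); an
external mapper can be adapted to it. Short-fragment checks (100 bp GCS
flanks, 200 bp post-splice junctions) use edlib infix alignment instead,
where per-base edit distance is the right notion of identity.

## Thresholds

| parameter | default | units | rationale |
|---|---|---|---|
| `min_run` | 10 | bp | smallest placeholder gap in practice is 25 bp; 10 tolerates donor dialects while ignoring isolated Ns |
| `arbitrary_lengths` | {25, 200} | bp | placeholder gap sizes used by the target assemblies |
| `anchor_min_identity` / `anchor_min_coverage` | 0.9 / 0.9 | fraction | tolerates subspecies-level divergence, rejects paralogs |
| `flank_len` | 100 | bp | donor context aligned back to the reference per GCS end |
| `min_flank_identity` | 0.95 | fraction | 5 mismatches in 100 bp; strict enough to reject repeat-array decoys |
| `adjacency_tol` | 20 | bp | how far a flank may land from the replaced span's end; absorbs indel jitter |
| `post_flank_len` | 200 | bp | junction fragments re-verified after splicing |
| `junction_window` | 50 | bp | N-free zone required around gap-close junctions |
| `min_support` | 3 | donors | "more than two assemblies" consensus for scaffold placement |
| `telomere_window` / `telomere_min_density` / `terminal_zone` | 1000 bp / 0.4 / 10 kb | — | a real telomeric array saturates a 1 kb window; 0.4 is far above the ~0.01 background of random sequence |
| `redundancy_min_coverage` / `redundancy_min_identity` | 0.9 / 0.98 | fraction | a scaffold must be near-wholly and near-exactly represented inside inserted sequence before deletion |

All are exposed in `PipelineConfig` and printed by `gapmend show-config`.

## Design choices that were genuinely open

* **"Best coverage" for ranking competing GCSs** is operationalized as
  highest mean per-base depth over the candidate's donor span, with
  coefficient of variation as tie-break (uniformly covered beats spiky).
  Depth tracks are consumed per *donor* assembly, since that is where the
  candidate's bases live before splicing. Breadth-of-coverage and
  uniformity-first policies were considered; mean-then-CV is reported as a
  policy, not a claim that it reconstructs any particular published
  selection.
* **One splice pass.** All accepted edits (gap closures, telomere grafts,
  scaffold placements) are expressed in original reference coordinates and
  applied in a single right-to-left pass. Decision stages still run in
  order (closures → placement → telomeres), and a later decision whose
  target overlaps an accepted edit is quarantined with a reason rather than
  composed through a second liftover round. This keeps every ledger row in
  one coordinate frame at the cost of refusing (rare) stacked edits.
* **Genes overlapping replaced spans are re-anchored**, not proportionally
  interpolated: their sequence changed, so only re-alignment against the
  corrected assembly is meaningful. Failures are reported, never silently
  dropped.
* **Scaffolds that align well but outside inserted spans are retained.**
  Such a scaffold was already redundant in the *uncorrected* assembly;
  deleting it is an upstream assembly decision, not a consequence of this
  curation.
* **Corrected sequences are renamed `cor_<id>`**, following the convention
  used for published corrected chromosome accessions; untouched records
  keep their ids.

## The synthetic truth set

`synthetic_fixtures` generates the study conditions end to end: truth
chromosomes with CCTAA/TTAGG telomeric arrays at the ends, uniformly spaced
unique gene-length segments, and tandem repeat arrays (5–50 bp motifs, one
duplicated across chromosomes as a paralogy decoy) planted inside future
gap regions — real assembly gaps sit in repeat-enriched sequence, and the
repeats are what make flank validation a meaningful test rather than a
formality.

Default conditions: 3 chromosomes × ~500 kb, 50 genes each (1.5–3 kb), 12
planted gaps per genome — seven arbitrary (25/200 bp), five estimated
(1–5 kb), three inside gene bodies, one at a chromosome start (no upstream
anchor), one whose upstream anchor gene is deleted from every donor — two
truncated right telomeres, three redundant scaffolds (copies of sequence
inside replaced regions) plus two novel random scaffolds, four donors (two
`reassembly` at divergence 0, two `alternative` at 1% substitutions), and
per-donor Poisson(30) depth with two forced-low 5 kb dropout windows.
Every planted feature is recorded with exact coordinates in both the truth
and degraded frames, so tests assert recovery, not plausibility; all output
is a pure function of (config, seed).

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: structural rearrangements beyond local
inversions, segmental duplications of gene-bearing regions, assembly
consensus errors clustered at contig joins, heterozygosity, and realistic
long-read error profiles (depth is Poisson per base, not read placement).
Real curation also involved manual inspection of competing candidates;
`gapmend` automates the decision rules, not the judgment calls.

## Numerical and degenerate-input behavior

* Coordinates are 0-based half-open everywhere internally; 1-based
  inclusive only at GFF3/depth file boundaries (single conversion point).
* Depth CV is defined as 0 when the mean is 0 (an all-zero window is
  uniform dropout; the mean term already ranks it last).
* Candidate ranking is a total order (class, −mean depth, CV, GCS length,
  donor id), so selection is invariant under permutation of donors.
* Ties in flank-gene assignment break lexicographically by gene id; gap ids
  are numbered per sequence left to right — reruns are bit-stable.
* Events must be non-overlapping per sequence and refer to pre-edit
  coordinates; re-applying an applied event list is an error by design.
* A flank falling off a donor sequence end is *unassessable*: the candidate
  stays unvalidated (with a warning) rather than being accepted or
  rejected on one-sided evidence. The same logic accepts telomere grafts
  and placed scaffolds at post-splice check with an explanatory note, since
  no reference context exists on one side.

## Problem sizes

The shipped test suite runs the full pipeline on the default 1.5 Mb truth
set across 20 seeds and on a ~120 kb set for unit-level checks; the
acceptance script runs one full default-size pipeline plus the
closure-manifest bookkeeping. These sizes give every stage multiple planted
events per run while keeping a complete suite execution in the low minutes
on one CPU.

## Known limitations

* The census counts chromosome-role records only by default; N-runs inside
  unplaced scaffolds are not part of the gap census (configurable).
* Exon-level reconciliation of donor vs reference gene structure inside
  replaced regions is out of scope; lifted annotations give gene bodies.
* The identity estimate of the k-mer chainer is a filter statistic, not an
  alignment identity; downstream consumers needing true identity should
  re-align the reported interval.
* Telomere recovery requires a unique terminal anchor gene; chromosomes
  whose last gene is duplicated in every donor stay unrecovered (reported).
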