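# gapmend

Assembly-to-assembly curation of chromosome-level reference genomes:
close polyN assembly gaps with **gap-closing sequences (GCSs)** extracted
from donor assemblies, recover missing distal telomeres, place unlocalized
scaffolds by gene-order consensus, drop scaffolds the edits make redundant,
and emit a corrected assembly with a lifted annotation and a complete,
auditable edit ledger.

The approach is the one used to correct the honey bee (*Apis mellifera*)
reference Amel_HAv_3.1, which carries 51 unresolved gaps (17 of them
placeholder runs of exactly 25 or 200 bp), 160 unplaced/unlocalized
scaffolds and two missing distal telomeres. Given independent long-read
assemblies of the same genome — re-assemblies built from the reference's own
reads, or assemblies of other subspecies — most of those defects can be
repaired without touching a single read: the genes flanking each gap act as
markers that locate the corresponding intact region in a donor.

## Method

For a reference *R* with annotation *G* and donor assemblies
*D₁ … Dₙ* (each labeled `reassembly` or `alternative`):

1. **Gap census.** Maximal N-runs ≥ `min_run` (default 10 bp) are
   detected per chromosome, classified *arbitrary* (length ∈ {25, 200}) or
   *estimated*, and given gene context: the nearest gene ending at or
   before the gap (upstream anchor *u*), the nearest gene starting at or
   after it (downstream anchor *d*), and a containing gene when the gap sits
   inside a gene body.
2. **Anchoring.** Each anchor gene is located in each donor with a
   deterministic exact-k-mer seed-and-chain aligner (k = 21, longest-
   increasing-subsequence collinear chaining, repeat k-mers masked at 50
   target occurrences). A gene is a usable anchor only when it maps
   uniquely with coverage ≥ 0.9 and estimated identity ≥ 0.9; duplicated
   genes are excluded — a duplicated marker localizes nothing.
3. **GCS extraction.** For an intergenic gap, the donor span from the
   coordinate matching end(*u*) to the coordinate matching start(*d*)
   replaces the same reference span (reverse-complemented when the donor
   region is inverted). A within-gene gap swaps in the donor's complete
   gene body. Donor spans containing their own N-runs are rejected.
4. **Flank validation.** The 100 bp of donor sequence immediately outside
   each GCS end must align back to the reference at ≥ 0.95 identity,
   landing within 20 bp of the replaced span's ends — this is what rejects
   candidates pulled from paralogous repeat arrays.
5. **Ranking.** Among validated candidates: a `reassembly`-class donor
   (rebuilt from the reference's own reads) beats any `alternative`; within
   a class, higher mean read depth over the donor span wins, then lower
   depth CV, then shorter GCS.
6. **Splicing + liftover.** Accepted edits are applied right-to-left per
   sequence; a liftover chain maps old to corrected coordinates, shifts
   untouched genes and re-anchors genes whose bodies were replaced. Each
   splice is re-verified post hoc: the 200 bp just inside each junction
   must align back adjacent to the replaced span, and gap-close junctions
   must be N-free.
7. **Telomeres.** Chromosome ends are scanned for the insect telomeric
   repeat (TTAGG / CCTAA) as windowed motif density (1 kb windows, call
   threshold 0.4 within the terminal 10 kb). A truncated end is regrafted
   from a donor whose matching end is telomeric, anchored on the terminal
   gene, so the last-gene-to-end distance afterwards equals the donor's.
8. **Scaffolds.** A scaffold carrying annotated genes is placed where at
   least `min_support` (default 3) donors agree on chromosome, flanking
   gene pair and orientation; a consensus site overlapping a gap closes
   it. After all edits, scaffolds aligning ≥ 0.9 of their length at
   ≥ 0.98 identity *inside inserted spans* are redundant and removed.

Every stage failure quarantines the gap or scaffold concerned with a
recorded reason; the run never aborts.

## Worked example

The package ships a seeded synthetic truth-set generator, so the whole
pipeline can be exercised without downloads:

```bash
gapmend simulate --out-dir fixtures --seed 1
gapmend census --reference fixtures/reference.fasta --gff fixtures/genes.gff3
```

```json
{
  "count": 12,
  "count_arbitrary": 7,
  "count_estimated": 5,
  "min_length": 25,
  "max_length": 5000,
  "total_length": 13200,
  "count_within_genes": 3,
  "count_unclosable": 1
}
```

Twelve planted gaps: seven placeholder (25/200 bp) runs, five
estimated-size runs, three inside gene bodies, one at a chromosome start
with no upstream anchor (unclosable by this method). Then run the curation
against the four donors (two divergence-0 re-assemblies, two alternative
assemblies at 1% divergence):

```bash
gapmend run --reference fixtures/reference.fasta --gff fixtures/genes.gff3 \
    --scaffold-list fixtures/scaffolds.tsv \
    --donor reFlye=fixtures/donor_reFlye.fasta:reassembly \
    --donor reND=fixtures/donor_reND.fasta:reassembly \
    --donor altA=fixtures/donor_altA.fasta:alternative \
    --donor altB=fixtures/donor_altB.fasta:alternative \
    --out-dir out
```

```
closed 10 gaps (11675 bp), telomeres 14440 bp, scaffolds 0 bp; total resolved 26115 bp
```

All ten closable gaps close (11,675 bp of N-runs resolved), both truncated
telomeres are regrafted (14,440 bp), the two unclosable gaps stay open with
recorded reasons (`no flanking anchors (sequence boundary)`,
`no anchored candidate`), and the three planted redundant scaffolds are
deleted while the two novel ones are retained. The edit ledger
(`out/ledger.tsv`) records every splice in original coordinates:

```
seq_id  old_start  old_end  action     donor   donor_seq  donor_start  donor_end  orientation  inserted_bp  event_id
chr1    105169     112288   gap_close  reFlye  chr1       105169       112863     +            7694         close_chr1_gap2
chr1    203615     211309   gap_close  reFlye  chr1       204190       211884     +            7694         close_chr1_gap3
chr1    298968     301168   gap_close  reFlye  chr1       299543       302043     +            2500         close_chr1_gap4
```

Because the winning donors are divergence-0 re-assemblies, the corrected
chromosomes match the simulation's truth genome base for base outside the
two unclosable gaps.

`gapmend summarize` reproduces the published bookkeeping of the honey-bee
curation from the packaged closure manifest: 13 gaps closed, 327,337 bp in
total, largest 158,704 bp.

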