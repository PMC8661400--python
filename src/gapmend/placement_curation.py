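"""Scaffold placement by gene-order consensus, telomere recovery, and
redundancy removal.

Placement: an unplaced/unlocalized scaffold carrying annotated genes is
located in each donor assembly through its gene anchors.  Each donor that
contains the scaffold's genes as a clean block, flanked by uniquely anchored
chromosome genes, votes for an insertion site on the reference (a
chromosome, the flanking gene pair, an orientation).  A site supported by at
least ``min_support`` donors is accepted; if it overlaps a censused gap the
scaffold doubles as a gap-closing sequence.

Telomeres: the insect telomeric repeat (TTAGG on the forward strand of the
distal end, CCTAA on the proximal) is detected as windowed motif density.  A
chromosome end with no dense telomeric window in its terminal zone is a
candidate for recovery: the terminal anchor gene is located in a donor whose
matching end *is* telomeric, and the reference span from the anchor's outer
boundary to the sequence end is replaced by the donor's span, so the
anchor-to-end distance afterwards equals the donor's.

Redundancy: after correction, scaffolds whose sequence aligns almost
entirely inside the newly inserted spans are duplicates of sequence now
represented on chromosomes and are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .assembly_io import Assembly, GeneModel, SeqEntry, revcomp
from .anchor_synteny import AnchorHit, KmerAligner, anchor_gene
from .gap_census import GapRecord
from .splice_editor import LiftoverChain, SpliceEvent

TELOMERE_MOTIFS = ("TTAGG", "CCTAA")
DEFAULT_WINDOW = 1000
DEFAULT_MIN_DENSITY = 0.4
DEFAULT_TERMINAL_ZONE = 10_000

PLACEMENT_ACTIONS = (
    "place", "close_gap", "append_telomere", "redundant", "retained", "unresolved",
)


@dataclass
class PlacementDecision:
    scaffold_id: str
    action: str
    target_seq_id: str | None = None
    target_interval: tuple[int, int] | None = None
    orientation: str | None = None
    supporting_assemblies: int = 0
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.action not in PLACEMENT_ACTIONS:
            raise ValueError(f"unknown placement action {self.action!r}")


@dataclass
class TelomereScan:
    seq_id: str
    window: int
    densities: np.ndarray  # combined motif coverage per tiling window
    left_call: str  # present | absent
    right_call: str

    def distal_call(self, end: str) -> str:
        return self.left_call if end == "left" else self.right_call


def motif_coverage(sequence: str, motifs: tuple[str, ...] = TELOMERE_MOTIFS) -> np.ndarray:
    """Boolean per-base mask: covered by a non-overlapping motif match."""
    covered = np.zeros(len(sequence), dtype=bool)
    for motif in motifs:
        for m in re.finditer(re.escape(motif), sequence):
            covered[m.start() : m.end()] = True
    return covered


def scan_telomeres(
    assembly: Assembly,
    motifs: tuple[str, ...] = TELOMERE_MOTIFS,
    window: int = DEFAULT_WINDOW,
    min_density: float = DEFAULT_MIN_DENSITY,
    terminal_zone: int = DEFAULT_TERMINAL_ZONE,
    roles: tuple[str, ...] = ("chromosome",),
) -> dict[str, TelomereScan]:
    """Windowed telomere-motif density and a present/absent call per end.

    Windows tile each sequence left to right (the last window may be
    partial; its density is over its actual length).  An end is called
    *present* when any window lying within ``terminal_zone`` of that end
    reaches ``min_density`` combined motif coverage.
    """
    scans: dict[str, TelomereScan] = {}
    for rec in assembly:
        if rec.role not in roles:
            continue
        covered = motif_coverage(rec.sequence, motifs)
        n = len(rec.sequence)
        starts = np.arange(0, n, window)
        densities = np.array(
            [covered[s : min(n, s + window)].mean() for s in starts]
        )
        left = densities[(starts < terminal_zone)]
        ends = np.minimum(starts + window, n)
        right = densities[(ends > n - terminal_zone)]
        scans[rec.seq_id] = TelomereScan(
            seq_id=rec.seq_id,
            window=window,
            densities=densities,
            left_call="present" if len(left) and left.max() >= min_density else "absent",
            right_call="present" if len(right) and right.max() >= min_density else "absent",
        )
    return scans


class DuplicatedAnchorError(ValueError):
    """The terminal anchor gene hits multiple donor loci and cannot localize
    a telomere graft."""


def recover_telomere(
    chromosome: SeqEntry,
    genes: list[GeneModel],
    reference: Assembly,
    donor_id: str,
    donor: Assembly,
    aligner: KmerAligner,
    end: str = "right",
    motifs: tuple[str, ...] = TELOMERE_MOTIFS,
    window: int = DEFAULT_WINDOW,
    min_density: float = DEFAULT_MIN_DENSITY,
    terminal_zone: int = DEFAULT_TERMINAL_ZONE,
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
) -> SpliceEvent | None:
    """Propose a telomere graft for one chromosome end, or None.

    Preconditions checked here: the reference end must lack a telomeric
    call, the terminal anchor gene must anchor uniquely in the donor, and
    the donor sequence beyond the anchor (toward the matching end) must be
    telomeric.  A duplicated anchor raises :class:`DuplicatedAnchorError` —
    a duplicated terminal gene localizes nothing.
    """
    if end not in ("left", "right"):
        raise ValueError("end must be 'left' or 'right'")
    on_chrom = [g for g in genes if g.seq_id == chromosome.seq_id]
    if not on_chrom:
        return None
    scan = scan_telomeres(
        Assembly([chromosome]), motifs, window, min_density, terminal_zone,
        roles=(chromosome.role,),
    )[chromosome.seq_id]
    if scan.distal_call(end) == "present":
        return None
    anchor = (
        max(on_chrom, key=lambda g: g.end) if end == "right"
        else min(on_chrom, key=lambda g: g.start)
    )
    status, hit = anchor_gene(
        anchor, reference, donor_id, aligner,
        min_identity=min_identity, min_coverage=min_coverage,
    )
    if status == "duplicated":
        raise DuplicatedAnchorError(
            f"anchor gene {anchor.gene_id!r} is duplicated in donor {donor_id!r}"
        )
    if status != "unique":
        return None

    donor_seq = donor.sequence(hit.donor_seq_id)
    # the donor end matching the reference end, given relative orientation
    toward_right = (end == "right") == (hit.strand == "+")
    if toward_right:
        graft = donor_seq[hit.end :]
        donor_interval = (hit.end, len(donor_seq))
        donor_terminal = donor_seq[-terminal_zone:]
    else:
        graft = donor_seq[: hit.start]
        donor_interval = (0, hit.start)
        donor_terminal = donor_seq[:terminal_zone]
    if hit.strand == "-":
        graft = revcomp(graft)
    if not graft:
        return None
    covered = motif_coverage(donor_terminal, motifs)
    dens = [
        covered[s : s + window].mean()
        for s in range(0, max(1, len(donor_terminal) - window + 1), window)
    ]
    if not dens or max(dens) < min_density:
        return None

    if end == "right":
        replaced = (anchor.end, len(chromosome.sequence))
    else:
        replaced = (0, anchor.start)
    return SpliceEvent(
        event_id=f"telomere_{chromosome.seq_id}_{end}",
        seq_id=chromosome.seq_id,
        replaced_interval=replaced,
        replacement=graft,
        event_type="telomere_add",
        donor_id=donor_id,
        donor_seq_id=hit.donor_seq_id,
        donor_interval=donor_interval,
        orientation=hit.strand,
    )


@dataclass
class _DonorVote:
    chromosome: str
    left_gene: str | None
    right_gene: str | None
    orientation: str


def consensus_place_scaffold(
    scaffold: SeqEntry,
    scaffold_genes: list[GeneModel],
    scaffold_assembly: Assembly,
    ref_genes: list[GeneModel],
    donor_anchor_tables: dict[str, dict[str, AnchorHit]],
    donor_aligners: dict[str, KmerAligner],
    gaps: list[GapRecord] | None = None,
    min_support: int = 3,
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
) -> PlacementDecision:
    """Vote a scaffold's destination from its gene neighborhood in donors.

    ``donor_anchor_tables`` maps donor id -> {reference gene id -> AnchorHit}
    for chromosome genes (precomputed once per donor);
    ``donor_aligners`` provides the per-donor aligner used to anchor the
    scaffold's own genes.
    """
    genes_on = [g for g in scaffold_genes if g.seq_id == scaffold.seq_id]
    if not genes_on:
        return PlacementDecision(scaffold.seq_id, "unresolved", notes=["no_markers"])
    genes_on.sort(key=lambda g: g.start)
    ref_gene_by_id = {g.gene_id: g for g in ref_genes}

    votes: list[_DonorVote] = []
    notes: list[str] = []
    for donor_id, aligner in donor_aligners.items():
        hits: list[AnchorHit] = []
        ok = True
        for g in genes_on:
            status, hit = anchor_gene(
                g, scaffold_assembly, donor_id, aligner,
                min_identity=min_identity, min_coverage=min_coverage,
            )
            if status != "unique":
                notes.append(f"{donor_id}: gene {g.gene_id} {status}")
                ok = False
                break
            hits.append(hit)
        if not ok or not hits:
            continue
        seqs = {h.donor_seq_id for h in hits}
        strands = {h.strand for h in hits}
        if len(seqs) > 1 or len(strands) > 1:
            notes.append(f"{donor_id}: scaffold genes not a clean block")
            continue
        orientation = strands.pop()
        donor_seq_id = seqs.pop()
        block_lo = min(h.start for h in hits)
        block_hi = max(h.end for h in hits)
        # order consistency inside the block
        by_donor = sorted(hits, key=lambda h: h.start)
        expected = [g.gene_id for g in genes_on]
        observed = [h.gene_id for h in by_donor]
        if observed != (expected if orientation == "+" else expected[::-1]):
            notes.append(f"{donor_id}: internal gene order discordant")
            continue
        # flanking chromosome genes in this donor
        table = donor_anchor_tables.get(donor_id, {})
        same_seq = [h for h in table.values() if h.donor_seq_id == donor_seq_id]
        lefts = [h for h in same_seq if h.end <= block_lo]
        rights = [h for h in same_seq if h.start >= block_hi]
        left_hit = max(lefts, key=lambda h: h.end) if lefts else None
        right_hit = min(rights, key=lambda h: h.start) if rights else None
        vote = _vote_from_neighbors(
            left_hit, right_hit, orientation, ref_gene_by_id, notes, donor_id
        )
        if vote is not None:
            votes.append(vote)

    if not votes:
        return PlacementDecision(
            scaffold.seq_id, "unresolved", notes=notes + ["no donor votes"]
        )
    tally: dict[tuple, int] = {}
    for v in votes:
        key = (v.chromosome, v.left_gene, v.right_gene, v.orientation)
        tally[key] = tally.get(key, 0) + 1
    (chrom, left_g, right_g, orient), support = max(tally.items(), key=lambda kv: kv[1])
    if support < min_support:
        return PlacementDecision(
            scaffold.seq_id, "unresolved", supporting_assemblies=support,
            notes=notes + [f"insufficient support ({support} < {min_support})"],
        )
    lo = ref_gene_by_id[left_g].end if left_g else 0
    hi = ref_gene_by_id[right_g].start if right_g else None
    if hi is None:
        notes.append("no right flanking gene; interval open-ended")
        hi = lo
    action = "place"
    for gap in gaps or []:
        if gap.seq_id == chrom and gap.start < hi and lo < gap.end:
            action = "close_gap"
            notes.append(f"consensus interval overlaps {gap.gap_id}")
            break
    return PlacementDecision(
        scaffold.seq_id, action,
        target_seq_id=chrom, target_interval=(lo, hi), orientation=orient,
        supporting_assemblies=support, notes=notes,
    )


def _vote_from_neighbors(left_hit, right_hit, orientation, ref_gene_by_id, notes, donor_id):
    if left_hit is None and right_hit is None:
        notes.append(f"{donor_id}: no flanking chromosome anchors")
        return None
    neighbor_strands = {h.strand for h in (left_hit, right_hit) if h is not None}
    if len(neighbor_strands) > 1:
        notes.append(f"{donor_id}: flanking anchors disagree on strand")
        return None
    region_strand = neighbor_strands.pop()
    chroms = {
        ref_gene_by_id[h.gene_id].seq_id for h in (left_hit, right_hit) if h is not None
    }
    if len(chroms) > 1:
        notes.append(f"{donor_id}: flanking anchors on different chromosomes")
        return None
    # donor-left vs reference-left depends on how the donor region maps back
    left_gene = left_hit.gene_id if left_hit else None
    right_gene = right_hit.gene_id if right_hit else None
    rel = orientation
    if region_strand == "-":
        left_gene, right_gene = right_gene, left_gene
        rel = "-" if rel == "+" else "+"
    return _DonorVote(
        chromosome=chroms.pop(), left_gene=left_gene, right_gene=right_gene,
        orientation=rel,
    )


def detect_redundant(
    scaffolds: list[SeqEntry],
    corrected: Assembly,
    chain: LiftoverChain,
    aligner: KmerAligner | None = None,
    min_coverage: float = 0.9,
    min_identity: float = 0.98,
) -> list[PlacementDecision]:
    """Flag scaffolds whose sequence now lives inside inserted spans.

    A scaffold is redundant when at least ``min_coverage`` of it aligns to
    the corrected assembly at ``min_identity`` or better *and* the aligned
    footprint intersects sequence inserted by the curation; a scaffold that
    aligns well entirely outside inserted spans is retained (it was already
    represented before curation and removing it is not this tool's call).
    """
    if aligner is None:
        aligner = KmerAligner(corrected)
    spans_by_new: dict[str, list[tuple[int, int]]] = {
        chain.new_ids[old]: [(lo, hi) for lo, hi, _ in chain.inserted_spans(old)]
        for old in chain.events
    }
    decisions: list[PlacementDecision] = []
    for scaffold in scaffolds:
        try:
            hits = aligner.map(scaffold.sequence, max_hits=10)
        except ValueError:
            decisions.append(
                PlacementDecision(scaffold.seq_id, "retained", notes=["unalignable"])
            )
            continue
        # a scaffold still present in the corrected assembly trivially hits
        # its own record; only cross-record alignments count as evidence
        good = [
            h for h in hits
            if h.identity >= min_identity and h.target_id != scaffold.seq_id
        ]
        coverage = min(1.0, sum(h.coverage for h in good))
        in_inserted = any(
            lo < h.t_end and h.t_start < hi
            for h in good
            for lo, hi in spans_by_new.get(h.target_id, [])
        )
        if coverage >= min_coverage and in_inserted:
            decisions.append(
                PlacementDecision(
                    scaffold.seq_id, "redundant",
                    notes=[f"coverage={coverage:.3f} inside inserted span"],
                )
            )
        elif coverage >= min_coverage:
            decisions.append(
                PlacementDecision(
                    scaffold.seq_id, "retained",
                    notes=[f"coverage={coverage:.3f} but outside inserted spans"],
                )
            )
        else:
            decisions.append(
                PlacementDecision(
                    scaffold.seq_id, "retained", notes=[f"coverage={coverage:.3f}"]
                )
            )
    return decisions
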