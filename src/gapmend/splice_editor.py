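"""Application of replacement edits and the coordinate liftover they induce.

Every accepted curation action — pasting a gap-closing sequence, grafting a
telomere, inserting a placed scaffold — is a :class:`SpliceEvent`: replace
``replaced_interval`` (old coordinates) with a given sequence.  Events on
one sequence must not overlap and always refer to *pre-edit* coordinates;
they are applied right-to-left so no event's coordinates need rewriting as
earlier (leftward) edits change sequence length.  The resulting
:class:`LiftoverChain` translates old positions to corrected positions (and
back), which is how untouched annotations are carried over and how the edit
ledger stays auditable in a single coordinate frame.

Corrected sequences keep their original id with a ``cor_`` prefix, the
convention used for published corrected chromosome accessions.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace as dc_replace

import edlib

from .assembly_io import Assembly, GeneModel, SeqEntry


class _InsideEdit:
    """Sentinel: the queried old position falls inside a replaced interval."""

    def __repr__(self) -> str:  # pragma: no cover
        return "INSIDE_EDIT"


INSIDE_EDIT = _InsideEdit()


@dataclass
class SpliceEvent:
    """One replacement edit in pre-edit coordinates."""

    event_id: str
    seq_id: str
    replaced_interval: tuple[int, int]
    replacement: str
    event_type: str = "gap_close"  # gap_close | telomere_add | scaffold_place
    donor_id: str | None = None
    donor_seq_id: str | None = None
    donor_interval: tuple[int, int] | None = None
    orientation: str = "+"
    applied: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.replaced_interval
        if lo < 0 or hi < lo:
            raise ValueError(f"event {self.event_id}: bad interval [{lo}, {hi})")

    @property
    def inserted_length(self) -> int:
        return len(self.replacement)

    @property
    def replaced_length(self) -> int:
        return self.replaced_interval[1] - self.replaced_interval[0]

    @property
    def delta(self) -> int:
        return self.inserted_length - self.replaced_length

    @property
    def sort_key(self) -> tuple:
        return (self.seq_id, self.replaced_interval[0], self.event_id)


class LiftoverChain:
    """Old -> new coordinate map induced by a set of applied events."""

    def __init__(self) -> None:
        self.events: dict[str, list[SpliceEvent]] = {}
        self.new_ids: dict[str, str] = {}
        self._starts: dict[str, list[int]] = {}
        self._cumdelta: dict[str, list[int]] = {}

    def add_sequence(self, seq_id: str, new_id: str, events: list[SpliceEvent]) -> None:
        events = sorted(events, key=lambda e: e.replaced_interval[0])
        self.events[seq_id] = events
        self.new_ids[seq_id] = new_id
        starts, cum = [], []
        acc = 0
        for e in events:
            starts.append(e.replaced_interval[0])
            acc += e.delta
            cum.append(acc)
        self._starts[seq_id] = starts
        self._cumdelta[seq_id] = cum

    def lift_position(self, seq_id: str, old_pos: int):
        """New coordinate of an old position, or INSIDE_EDIT."""
        if seq_id not in self.events:
            raise KeyError(f"unknown sequence {seq_id!r} in liftover chain")
        events = self.events[seq_id]
        i = bisect_right(self._starts[seq_id], old_pos) - 1
        if i < 0:
            return old_pos
        lo, hi = events[i].replaced_interval
        if old_pos < hi:
            return INSIDE_EDIT
        return old_pos + self._cumdelta[seq_id][i]

    def lift_back(self, seq_id: str, new_pos: int):
        """Old coordinate of a corrected position, or INSIDE_EDIT when the
        position falls inside inserted sequence."""
        if seq_id not in self.events:
            raise KeyError(f"unknown sequence {seq_id!r} in liftover chain")
        acc = 0
        for e in self.events[seq_id]:
            lo, hi = e.replaced_interval
            new_lo = lo + acc
            new_hi = new_lo + e.inserted_length
            if new_pos < new_lo:
                return new_pos - acc
            if new_pos < new_hi:
                return INSIDE_EDIT
            acc += e.delta
        return new_pos - acc

    def inserted_spans(self, seq_id: str) -> list[tuple[int, int, SpliceEvent]]:
        """Corrected-coordinate spans occupied by inserted sequence."""
        spans = []
        acc = 0
        for e in self.events.get(seq_id, []):
            lo, _ = e.replaced_interval
            new_lo = lo + acc
            spans.append((new_lo, new_lo + e.inserted_length, e))
            acc += e.delta
        return spans

    def total_delta(self, seq_id: str) -> int:
        cum = self._cumdelta.get(seq_id, [])
        return cum[-1] if cum else 0


def _check_events(assembly: Assembly, events: list[SpliceEvent]) -> dict[str, list[SpliceEvent]]:
    by_seq: dict[str, list[SpliceEvent]] = {}
    for e in events:
        if e.applied:
            raise ValueError(
                f"event {e.event_id} was already applied; events reference "
                "pre-edit coordinates and cannot be replayed"
            )
        if e.seq_id not in assembly:
            raise KeyError(f"event {e.event_id}: unknown sequence {e.seq_id!r}")
        lo, hi = e.replaced_interval
        if hi > assembly.length(e.seq_id):
            raise ValueError(
                f"event {e.event_id}: interval [{lo}, {hi}) outside "
                f"{e.seq_id!r} (length {assembly.length(e.seq_id)})"
            )
        by_seq.setdefault(e.seq_id, []).append(e)
    for seq_id, evs in by_seq.items():
        evs.sort(key=lambda e: e.replaced_interval[0])
        for a, b in zip(evs, evs[1:]):
            if a.replaced_interval[1] > b.replaced_interval[0]:
                raise ValueError(
                    f"overlapping events on {seq_id}: {a.event_id} and {b.event_id}"
                )
    return by_seq


def apply_splices(
    assembly: Assembly, events: list[SpliceEvent], prefix: str = "cor_"
) -> tuple[Assembly, LiftoverChain]:
    """Apply all events, returning the corrected assembly and its chain.

    Events are applied right-to-left within each sequence so every recorded
    interval stays valid in the original frame.  Edited sequences are renamed
    with ``prefix``; untouched records pass through unchanged (the chain
    still knows them, with an identity mapping).
    """
    by_seq = _check_events(assembly, events)
    chain = LiftoverChain()
    new_records: list[SeqEntry] = []
    for rec in assembly:
        evs = by_seq.get(rec.seq_id, [])
        if not evs:
            chain.add_sequence(rec.seq_id, rec.seq_id, [])
            new_records.append(rec)
            continue
        seq = rec.sequence
        for e in sorted(evs, key=lambda e: -e.replaced_interval[0]):
            lo, hi = e.replaced_interval
            seq = seq[:lo] + e.replacement + seq[hi:]
            e.applied = True
        new_id = prefix + rec.seq_id
        chain.add_sequence(rec.seq_id, new_id, evs)
        new_records.append(dc_replace(rec, seq_id=new_id, sequence=seq))
    return Assembly(new_records), chain


def lift_position(chain: LiftoverChain, seq_id: str, old_pos: int):
    return chain.lift_position(seq_id, old_pos)


@dataclass
class LiftedGene:
    gene: GeneModel | None
    original_id: str
    status: str  # shifted | re_anchored | failed_re_anchor | unlifted
    note: str = ""


def lift_annotation(
    genes: list[GeneModel],
    chain: LiftoverChain,
    corrected: Assembly | None = None,
    reference: Assembly | None = None,
    aligner=None,
    min_coverage: float = 0.8,
    min_identity: float = 0.9,
) -> list[LiftedGene]:
    """Carry an annotation across a set of applied edits.

    Genes whose bodies avoid every replaced interval are shifted
    arithmetically.  Genes overlapping a replaced interval cannot be shifted
    (their sequence changed) and are re-anchored by aligning the original
    gene sequence against the corrected assembly — the coordinate-level
    analogue of re-running an annotation liftover tool after editing.  No
    gene is silently dropped: failures are reported with status
    ``failed_re_anchor``.
    """
    from .anchor_synteny import KmerAligner, anchor_gene

    out: list[LiftedGene] = []
    need_anchor: list[GeneModel] = []
    for g in genes:
        if g.seq_id not in chain.events:
            out.append(LiftedGene(g, g.gene_id, "unlifted", "sequence not edited"))
            continue
        new_start = chain.lift_position(g.seq_id, g.start)
        new_end = chain.lift_position(g.seq_id, g.end - 1)
        if new_start is INSIDE_EDIT or new_end is INSIDE_EDIT or _spans_edit(chain, g):
            need_anchor.append(g)
            continue
        lifted = GeneModel(
            seq_id=chain.new_ids[g.seq_id],
            start=new_start,
            end=new_end + 1,
            gene_id=g.gene_id,
            strand=g.strand,
        )
        out.append(LiftedGene(lifted, g.gene_id, "shifted"))

    if need_anchor:
        if corrected is None or reference is None:
            out.extend(
                LiftedGene(None, g.gene_id, "failed_re_anchor", "no corrected assembly given")
                for g in need_anchor
            )
        else:
            if aligner is None:
                aligner = KmerAligner(corrected)
            for g in need_anchor:
                status, hit = anchor_gene(
                    g, reference, "corrected", aligner,
                    min_identity=min_identity, min_coverage=min_coverage,
                )
                if status == "unique":
                    lifted = GeneModel(
                        seq_id=hit.donor_seq_id,
                        start=hit.start,
                        end=hit.end,
                        gene_id=g.gene_id,
                        strand=g.strand if hit.strand == "+" else ("-" if g.strand == "+" else "+"),
                    )
                    out.append(LiftedGene(lifted, g.gene_id, "re_anchored"))
                else:
                    out.append(LiftedGene(None, g.gene_id, "failed_re_anchor", status))
    return out


def _spans_edit(chain: LiftoverChain, gene: GeneModel) -> bool:
    for e in chain.events.get(gene.seq_id, []):
        lo, hi = e.replaced_interval
        if gene.start < hi and lo < gene.end:
            return True
    return False


def post_splice_check(
    corrected: Assembly,
    reference: Assembly,
    event: SpliceEvent,
    chain: LiftoverChain,
    flank_len: int = 200,
    min_identity: float = 0.95,
    adjacency_tol: int = 20,
    junction_window: int = 50,
) -> tuple[str, list[str]]:
    """Verify one applied splice from the corrected sequence itself.

    The informative post-hoc signal is junction *continuity*: a gap-closing
    sequence overlaps reference sequence at both of its ends (the replaced
    span runs gene-boundary to gene-boundary, beyond the N-run), so the
    ``flank_len`` bases just inside each end of the inserted span must align
    back to the original reference landing adjacent to the replaced
    interval's ends.  An edit pasted at the wrong locus leaves inserted ends
    that match nothing near the junctions.  Gap-closing junctions must also
    be N-free within ``junction_window``.  Ends with no assessable reference
    context — a telomere graft runs past the old sequence end, a placed
    scaffold is sequence the reference never had — are noted, not failed.
    """
    notes: list[str] = []
    spans = {e.event_id: (lo, hi) for lo, hi, e in chain.inserted_spans(event.seq_id)}
    if event.event_id not in spans:
        return "fail", ["event not found in chain"]
    new_lo, new_hi = spans[event.event_id]
    cor_seq = corrected.sequence(chain.new_ids[event.seq_id])
    ref_seq = reference.sequence(event.seq_id)
    r_lo, r_hi = event.replaced_interval
    slack = adjacency_tol + 30

    if event.event_type == "gap_close":
        for j in (new_lo, new_hi):
            around = cor_seq[max(0, j - junction_window) : j + junction_window]
            if "N" in around:
                return "fail", notes + ["junction_n"]

    check_up = event.event_type in ("gap_close", "telomere_add") and r_lo > 0
    check_down = event.event_type == "gap_close" and r_hi < len(ref_seq)
    if event.event_type == "scaffold_place":
        notes.append("inserted sequence is novel; junction content not comparable")
    if not check_up and event.event_type != "scaffold_place":
        notes.append("upstream flank unassessable (sequence start)")
    if not check_down and event.event_type != "scaffold_place":
        notes.append("downstream flank unassessable (sequence end)")

    if check_up:
        inner_up = cor_seq[new_lo : new_lo + flank_len]
        w_lo = max(0, r_lo - slack)
        window = ref_seq[w_lo : min(len(ref_seq), r_lo + len(inner_up) + slack)]
        ident, loc_start = _infix_identity_start(inner_up, window, w_lo)
        if ident < min_identity or abs(loc_start - r_lo) > adjacency_tol:
            return "fail", notes + [f"junction_mismatch:upstream identity={ident:.3f}"]
    if check_down:
        inner_down = cor_seq[max(new_lo, new_hi - flank_len) : new_hi]
        w_lo = max(0, r_hi - len(inner_down) - slack)
        window = ref_seq[w_lo : min(len(ref_seq), r_hi + slack)]
        ident, loc_end = _infix_identity(inner_down, window, w_lo)
        if ident < min_identity or abs(loc_end - r_hi) > adjacency_tol:
            return "fail", notes + [f"junction_mismatch:downstream identity={ident:.3f}"]
    return "pass", notes


def _infix_identity(flank: str, window: str, offset: int) -> tuple[float, int]:
    res = edlib.align(flank, window, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0.0, -(10**9)
    loc = res["locations"][0]
    return max(0.0, 1.0 - res["editDistance"] / len(flank)), offset + loc[1] + 1


def _infix_identity_start(flank: str, window: str, offset: int) -> tuple[float, int]:
    res = edlib.align(flank, window, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return 0.0, -(10**9)
    loc = res["locations"][0]
    return max(0.0, 1.0 - res["editDistance"] / len(flank)), offset + loc[0]
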