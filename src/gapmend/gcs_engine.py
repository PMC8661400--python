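"""Extraction, validation and selection of gap-closing sequences (GCSs).

A GCS is the donor-assembly sequence spanning a reference gap, delimited by
the gap's flanking-gene anchors.  For an intergenic gap the replaced
reference span runs from the end of the upstream flanking gene to the start
of the downstream one; for a gap inside a gene the whole gene body is
replaced with the donor's complete copy.  Extracted candidates are validated
by re-aligning short donor flanks immediately outside the GCS back to the
reference: both flanks must match near-perfectly and land adjacent to the
replaced span, which rejects candidates pulled from paralogous repeat
arrays.  When several donors offer a validated GCS for the same gap, a
re-assembly of the reference's own reads is preferred over an alternative
assembly (it cannot introduce between-sample variation); within a class the
candidate with the best read-depth support wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .assembly_io import Assembly, DepthTrack, GeneModel, revcomp
from .anchor_synteny import AnchorHit
from .gap_census import GapRecord

SOURCE_CLASSES = ("reassembly", "alternative")

DEFAULT_FLANK_LEN = 100
DEFAULT_MIN_FLANK_IDENTITY = 0.95
DEFAULT_ADJACENCY_TOL = 20


@dataclass
class GCSCandidate:
    """A donor-derived replacement sequence for one gap."""

    gap_id: str
    donor_id: str
    source_class: str
    donor_seq_id: str
    donor_interval: tuple[int, int]
    strand: str  # donor orientation relative to the reference
    sequence: str
    ref_seq_id: str
    replaced_ref_interval: tuple[int, int]
    whole_gene: bool = False
    upstream_flank_identity: float | None = None
    downstream_flank_identity: float | None = None
    depth_mean: float | None = None
    depth_cv: float | None = None
    status: str = "candidate"  # candidate | validated | selected | rejected
    reason: str | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def replaced_length(self) -> int:
        a, b = self.replaced_ref_interval
        return b - a

    def reject(self, reason: str) -> "GCSCandidate":
        self.status = "rejected"
        self.reason = reason
        return self


def _has_n_run(seq: str, min_run: int) -> bool:
    return "N" * min_run in seq


def extract_gcs(
    gap: GapRecord,
    donor: Assembly,
    up_hit: AnchorHit,
    down_hit: AnchorHit,
    up_gene: GeneModel,
    down_gene: GeneModel,
    source_class: str = "alternative",
    min_run: int = 10,
) -> GCSCandidate:
    """Cut the candidate replacement sequence out of a donor assembly.

    For a within-gene gap pass the containing gene's single anchor as both
    ``up_hit`` and ``down_hit`` (and the gene as both gene arguments): the
    whole gene body is then replaced rather than the inter-anchor span.

    Failures are returned as rejected candidates (reason set), never raised:
    a gap with no usable candidate simply stays open.
    """
    if source_class not in SOURCE_CLASSES:
        raise ValueError(f"unknown source class {source_class!r}")
    whole_gene = up_hit is down_hit or (
        up_hit.gene_id == down_hit.gene_id and up_gene.gene_id == down_gene.gene_id
    )
    if whole_gene:
        replaced = (up_gene.start, up_gene.end)
    else:
        replaced = (up_gene.end, down_gene.start)

    def make(seq_id, interval, strand, sequence) -> GCSCandidate:
        return GCSCandidate(
            gap_id=gap.gap_id,
            donor_id=up_hit.donor_id,
            source_class=source_class,
            donor_seq_id=seq_id,
            donor_interval=interval,
            strand=strand,
            sequence=sequence,
            ref_seq_id=gap.seq_id,
            replaced_ref_interval=replaced,
            whole_gene=whole_gene,
        )

    if up_hit.donor_seq_id != down_hit.donor_seq_id:
        return make(up_hit.donor_seq_id, (0, 0), "+", "").reject("split_anchor")
    seq_id = up_hit.donor_seq_id
    if up_hit.strand != down_hit.strand:
        return make(seq_id, (0, 0), "+", "").reject("order_conflict")
    strand = up_hit.strand
    if whole_gene:
        lo, hi = up_hit.start, up_hit.end
    elif strand == "+":
        lo, hi = up_hit.end, down_hit.start
    else:
        # reference order appears reversed on the donor's forward strand
        lo, hi = down_hit.end, up_hit.start
    if lo >= hi:
        return make(seq_id, (lo, lo), strand, "").reject("order_conflict")
    donor_seq = donor.sequence(seq_id)[lo:hi]
    candidate = make(seq_id, (lo, hi), strand, donor_seq if strand == "+" else revcomp(donor_seq))
    if _has_n_run(donor_seq, min_run):
        return candidate.reject("donor_gapped")
    return candidate


def _flank_identity(
    flank: str,
    reference_window: str,
    window_offset: int,
) -> tuple[float, int, int]:
    """Best infix alignment of a flank inside a reference window.

    Returns (identity, match_start, match_end) with positions in the
    reference frame (window_offset added).
    """
    res = edlib.align(flank, reference_window, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0 or not res["locations"]:
        return 0.0, -1, -1
    loc = res["locations"][0]
    identity = max(0.0, 1.0 - dist / len(flank))
    return identity, window_offset + loc[0], window_offset + loc[1] + 1


def validate_flanks(
    candidate: GCSCandidate,
    reference: Assembly,
    donor: Assembly,
    flank_len: int = DEFAULT_FLANK_LEN,
    min_flank_identity: float = DEFAULT_MIN_FLANK_IDENTITY,
    adjacency_tol: int = DEFAULT_ADJACENCY_TOL,
) -> GCSCandidate:
    """Check that the donor context just outside the GCS matches the
    reference just outside the replaced span.

    The ``flank_len`` donor bases immediately upstream/downstream of the GCS
    (in the reference orientation) are aligned to the reference around the
    replaced interval.  The candidate is validated only when both flanks
    reach ``min_flank_identity`` and land within ``adjacency_tol`` of the
    replaced interval's ends; a flank that falls off the donor sequence end
    is recorded as unassessable and leaves the candidate unvalidated but not
    rejected.
    """
    if candidate.status == "rejected":
        return candidate
    donor_seq = donor.sequence(candidate.donor_seq_id)
    lo, hi = candidate.donor_interval
    a = min(flank_len, lo)                      # donor bases available left of GCS
    b = min(flank_len, len(donor_seq) - hi)     # and right
    ext = donor_seq[lo - a : hi + b]
    if candidate.strand == "-":
        ext = revcomp(ext)
        a, b = b, a
    gcs_len = hi - lo
    up_flank = ext[:a]
    down_flank = ext[a + gcs_len :]

    ref_seq = reference.sequence(candidate.ref_seq_id)
    r_lo, r_hi = candidate.replaced_ref_interval
    slack = adjacency_tol + 30
    unassessable = False

    if len(up_flank) < flank_len // 2:
        candidate.warnings.append("upstream flank unassessable (donor sequence end)")
        unassessable = True
    else:
        w_lo = max(0, r_lo - len(up_flank) - slack)
        ident, _, match_end = _flank_identity(up_flank, ref_seq[w_lo : r_lo + slack], w_lo)
        candidate.upstream_flank_identity = ident
        if ident < min_flank_identity or abs(match_end - r_lo) > adjacency_tol:
            return candidate.reject("flank_mismatch")

    if len(down_flank) < flank_len // 2:
        candidate.warnings.append("downstream flank unassessable (donor sequence end)")
        unassessable = True
    else:
        w_hi = min(len(ref_seq), r_hi + len(down_flank) + slack)
        ident, match_start, _ = _flank_identity(
            down_flank, ref_seq[max(0, r_hi - slack) : w_hi], max(0, r_hi - slack)
        )
        candidate.downstream_flank_identity = ident
        if ident < min_flank_identity or abs(match_start - r_hi) > adjacency_tol:
            return candidate.reject("flank_mismatch")

    if not unassessable:
        candidate.status = "validated"
    return candidate


def coverage_stats(track: DepthTrack, seq_id: str, interval: tuple[int, int]) -> tuple[float, float]:
    """Mean and coefficient of variation of per-base depth over an interval.

    CV = population standard deviation / mean, with CV defined as 0 when the
    mean is 0 (an all-zero window is perfectly uniform dropout, and ranking
    already penalizes it through the mean).
    """
    lo, hi = interval
    if hi <= lo:
        raise ValueError(f"empty interval [{lo}, {hi})")
    vec = track[seq_id]
    if lo < 0 or hi > len(vec):
        raise ValueError(f"interval [{lo}, {hi}) outside track for {seq_id!r}")
    window = vec[lo:hi].astype(np.float64)
    mean = float(window.mean())
    if mean == 0.0:
        return 0.0, 0.0
    return mean, float(window.std() / mean)


def attach_depth(candidate: GCSCandidate, track: DepthTrack | None) -> GCSCandidate:
    """Populate a candidate's depth stats from its donor's depth track."""
    if track is None or candidate.donor_seq_id not in track:
        return candidate
    lo, hi = candidate.donor_interval
    if hi > lo:
        candidate.depth_mean, candidate.depth_cv = coverage_stats(
            track, candidate.donor_seq_id, (lo, hi)
        )
    return candidate


_CLASS_RANK = {"reassembly": 0, "alternative": 1}


def rank_candidates(candidates: list[GCSCandidate]) -> GCSCandidate | None:
    """Pick the winning validated candidate for one gap.

    Order: (1) any re-assembly-class candidate beats all alternatives;
    (2) higher mean depth; (3) lower depth CV; (4) shorter GCS; (5)
    lexicographic donor id.  The key is total, so the selection is invariant
    under permutation of the input.  Returns None when nothing validated.
    """
    validated = [c for c in candidates if c.status == "validated"]
    if not validated:
        return None
    winner = min(
        validated,
        key=lambda c: (
            _CLASS_RANK[c.source_class],
            -(c.depth_mean if c.depth_mean is not None else 0.0),
            c.depth_cv if c.depth_cv is not None else 0.0,
            len(c.sequence),
            c.donor_id,
        ),
    )
    winner.status = "selected"
    return winner
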