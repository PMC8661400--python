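"""Gene anchoring between assemblies and gene-order comparison.

The pipeline needs one alignment primitive: given a query (a gene body, a
flank, a scaffold), find where it sits in a target assembly, on which
strand, and how well it matches.  That contract is deliberately small so an
external long-read mapper can be dropped in, but the built-in implementation
is a deterministic exact-k-mer seed-and-chain aligner:

1. every k-mer of the target is indexed (sorted-array index, binary-search
   lookup);
2. query k-mers on both strands are looked up, k-mers occurring more than
   ``max_occ`` times in the target are discarded (repeat masking);
3. seed pairs are chained by longest increasing subsequence on (query,
   target) positions, giving the best collinear chain per locus;
4. coverage is the fraction of the query's non-N bases covered by chained
   seeds; identity is estimated from the number of breaks in seed coverage
   along the chain (each break marks at least one mismatch event).

With k = 21, an isolated substitution destroys the k-mers overlapping it but
leaves flanking seeds intact, so at ~1% divergence chains stay contiguous
and the seed-coverage identity estimate tracks true identity closely.  The
estimate degrades quickly past ~3% divergence, which is the point: anchors
are meant to reject paralogs.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from .assembly_io import Assembly, GeneModel, revcomp

_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _v in zip(b"ACGT", range(4)):
    _ENCODE[_b] = _v

DEFAULT_K = 21
DEFAULT_MAX_OCC = 50
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_COVERAGE = 0.9


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mer codes and the positions where the window is N-free."""
    b = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(b)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    m = n - k + 1
    bb = b.astype(np.int64) & 3
    acc = np.zeros(m, dtype=np.int64)
    for j in range(k):
        acc = (acc << 2) | bb[j : j + m]
    is_n = np.concatenate(([0], np.cumsum(b < 0)))
    valid = (is_n[k:] - is_n[:-k]) == 0
    pos = np.flatnonzero(valid)
    return acc[pos], pos


@dataclass(frozen=True)
class RawHit:
    """One chained alignment of a query to a target sequence."""

    target_id: str
    t_start: int
    t_end: int
    strand: str  # query strand relative to target
    identity: float
    coverage: float
    q_start: int
    q_end: int
    n_seeds: int
    matched: int

    @property
    def score(self) -> tuple[float, float]:
        return (self.coverage, self.identity)


class _SeqIndex:
    def __init__(self, seq: str, k: int):
        codes, pos = _kmer_codes(seq, k)
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.sorted_pos = pos[order]

    def lookup(self, q_codes: np.ndarray, q_pos: np.ndarray, max_occ: int):
        """Return (query_pos, target_pos, masked_query_pos): seed pairs for
        all shared k-mers, plus the query positions whose k-mer was dropped
        for exceeding ``max_occ`` target occurrences (repeat masking)."""
        empty = np.empty(0, np.int64)
        if len(q_codes) == 0 or len(self.sorted_codes) == 0:
            return empty, empty, empty
        left = np.searchsorted(self.sorted_codes, q_codes, side="left")
        right = np.searchsorted(self.sorted_codes, q_codes, side="right")
        counts = right - left
        masked = q_pos[counts > max_occ]
        keep = (counts > 0) & (counts <= max_occ)
        if not keep.any():
            return empty, empty, masked
        l, c, q = left[keep], counts[keep], q_pos[keep]
        starts = np.cumsum(c) - c
        idx = np.repeat(l - starts, c) + np.arange(int(c.sum()))
        return np.repeat(q, c), self.sorted_pos[idx], masked


def _chain(q: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best collinear chain: longest subsequence strictly increasing in both
    query and target position.  Sorting by (q asc, t desc) reduces this to a
    strict LIS on t."""
    if len(q) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    order = np.lexsort((-t, q))
    qs, ts = q[order], t[order]
    tails: list[int] = []          # smallest tail t per chain length
    tails_idx: list[int] = []
    prev = np.full(len(ts), -1, dtype=np.int64)
    for i, val in enumerate(ts):
        pos = bisect_left(tails, val)
        if pos > 0:
            prev[i] = tails_idx[pos - 1]
        if pos == len(tails):
            tails.append(val)
            tails_idx.append(i)
        else:
            tails[pos] = val
            tails_idx[pos] = i
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(i)
        i = prev[i]
    chain.reverse()
    return qs[chain], ts[chain]


def _covered_bases(sorted_pos: np.ndarray, k: int) -> int:
    """Total bases covered by the union of k-length windows at sorted starts."""
    if len(sorted_pos) == 0:
        return 0
    gaps = np.diff(sorted_pos)
    return int(np.minimum(gaps, k).sum()) + k


class KmerAligner:
    """Anchoring aligner over a fixed target assembly.

    Satisfies the pipeline's aligner contract: ``map(query)`` returns scored
    strand-aware hits.  The target index is built once and reused across
    queries, so mapping many genes against one donor is cheap.
    """

    def __init__(self, target: Assembly, k: int = DEFAULT_K, max_occ: int = DEFAULT_MAX_OCC):
        if k < 4 or k > 31:
            raise ValueError("k must be in [4, 31] for 2-bit packing")
        self.k = k
        self.max_occ = max_occ
        self._indexes = {rec.seq_id: _SeqIndex(rec.sequence, k) for rec in target}

    def map(self, query: str, max_hits: int = 5, min_chain_fraction: float = 0.25) -> list[RawHit]:
        """Map a query against every target sequence, both strands.

        Returns hits sorted by (coverage, identity) descending.  Secondary
        hits at distinct target loci are reported (up to ``max_hits``), which
        is how duplicated anchors are detected.
        """
        k = self.k
        if len(query) < k:
            raise ValueError(f"query length {len(query)} < k={k}")
        query = query.upper()
        non_n = len(query) - query.count("N")
        if non_n == 0:
            raise ValueError("query is all N")
        fwd_codes, fwd_pos = _kmer_codes(query, k)
        rc = revcomp(query)
        rev_codes, rev_pos = _kmer_codes(rc, k)

        hits: list[RawHit] = []
        for target_id, index in self._indexes.items():
            fq, ft, fm = index.lookup(fwd_codes, fwd_pos, self.max_occ)
            rq, rt, rm = index.lookup(rev_codes, rev_pos, self.max_occ)
            hits.extend(
                self._extract_hits(
                    target_id, query, non_n, (fq, ft, fm), (rq, rt, rm),
                    max_hits, min_chain_fraction,
                )
            )
        hits.sort(key=lambda h: (-h.coverage, -h.identity, h.target_id, h.t_start))
        return hits[:max_hits]

    def _extract_hits(self, target_id, query, non_n, fwd, rev, max_hits, min_frac):
        k = self.k
        qlen = len(query)
        pools = {"+": [fwd[0], fwd[1]], "-": [rev[0], rev[1]]}
        masked = {"+": fwd[2], "-": rev[2]}
        out: list[RawHit] = []
        while len(out) < max_hits:
            best = None
            for strand, (pq, pt) in pools.items():
                cq, ct = _chain(pq, pt)
                if len(cq) == 0:
                    continue
                matched = _covered_bases(cq, k)
                if best is None or matched > best[3]:
                    best = (strand, cq, ct, matched)
            if best is None:
                break
            strand, cq, ct, matched = best
            if matched < max(2 * k, min_frac * non_n):
                break
            # repeat-masked query k-mers inside the chained span are bridged
            # by the collinear anchors around them: count their bases as
            # aligned for coverage (not for identity)
            m = masked[strand]
            bridged = m[(m >= cq[0]) & (m <= cq[-1])]
            if len(bridged):
                merged = np.unique(np.concatenate([cq, bridged]))
                matched_cov = _covered_bases(merged, k)
            else:
                matched_cov = matched
            span_q = int(cq[-1]) + k - int(cq[0])
            # N bases inside the chained query span carry no seeds; identity
            # is judged over informative bases only
            if strand == "+":
                q_lo, q_hi = int(cq[0]), int(cq[-1]) + k
            else:
                q_lo, q_hi = qlen - (int(cq[-1]) + k), qlen - int(cq[0])
            span_seq = query[q_lo:q_hi]
            informative = span_q - span_seq.count("N")
            # each break in seed coverage marks >= 1 mismatch event; an
            # isolated substitution kills k overlapping seeds but still
            # counts once, so this tracks true divergence far better than
            # the uncovered-base fraction would
            breaks = int((np.diff(cq) > k).sum())
            identity = (max(1, informative) - breaks) / max(1, informative)
            coverage = matched_cov / non_n
            t_lo, t_hi = int(ct[0]), int(ct[-1]) + k
            out.append(
                RawHit(
                    target_id=target_id,
                    t_start=t_lo,
                    t_end=t_hi,
                    strand=strand,
                    identity=min(1.0, identity),
                    coverage=min(1.0, coverage),
                    q_start=q_lo,
                    q_end=q_hi,
                    n_seeds=len(cq),
                    matched=matched,
                )
            )
            # mask out this locus and look for secondary hits
            for s, (pq, pt) in pools.items():
                keep = (pt + k <= t_lo) | (pt >= t_hi)
                pools[s] = [pq[keep], pt[keep]]
        return out


def builtin_anchor_align(query: str, target: str, k: int = DEFAULT_K) -> list[RawHit]:
    """One-shot alignment of a query against a single target string.

    Convenience wrapper over :class:`KmerAligner`; for repeated mapping
    against the same target, build the aligner once instead.
    """
    from .assembly_io import SeqEntry

    aligner = KmerAligner(Assembly([SeqEntry("target", target.upper())]), k=k)
    return aligner.map(query)


@dataclass(frozen=True)
class AnchorHit:
    """The located position of a reference gene in a donor assembly."""

    gene_id: str
    donor_id: str
    donor_seq_id: str
    start: int
    end: int
    strand: str  # orientation of the gene's reference strand in the donor
    identity: float
    coverage: float


def anchor_gene(
    gene: GeneModel,
    reference: Assembly,
    donor_id: str,
    aligner: KmerAligner,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[str, AnchorHit | None]:
    """Locate one gene in a donor; returns (status, hit).

    status is ``unique`` (usable anchor), ``absent`` (no hit above the
    identity/coverage floor) or ``duplicated`` (two or more passing loci —
    excluded as an anchor, since a duplicated marker localizes nothing).
    """
    seq = gene.sequence(reference)
    if len(seq) - seq.count("N") == 0:
        raise ValueError(f"gene {gene.gene_id!r} is all N in the reference")
    hits = aligner.map(seq)
    passing = [h for h in hits if h.coverage >= min_coverage and h.identity >= min_identity]
    if not passing:
        return "absent", None
    if len(passing) > 1:
        return "duplicated", None
    best = passing[0]
    return "unique", AnchorHit(
        gene_id=gene.gene_id,
        donor_id=donor_id,
        donor_seq_id=best.target_id,
        start=best.t_start,
        end=best.t_end,
        strand=best.strand,
        identity=best.identity,
        coverage=best.coverage,
    )


def map_gene_to_donor(
    gene: GeneModel,
    reference: Assembly,
    donor: Assembly,
    aligner: KmerAligner | None = None,
    donor_id: str = "donor",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> AnchorHit | None:
    """Best unique placement of a gene in a donor assembly, or None.

    Genes hitting two or more donor loci above threshold are treated as
    unplaceable (None), like absent genes: both are excluded as anchors.
    """
    if aligner is None:
        aligner = KmerAligner(donor)
    status, hit = anchor_gene(
        gene, reference, donor_id, aligner,
        min_identity=min_identity, min_coverage=min_coverage,
    )
    return hit if status == "unique" else None


@dataclass
class OrderComparison:
    """Gene order/orientation agreement for one region across assemblies."""

    region: str
    orders: dict[str, list[tuple[str, str]]]  # assembly id -> [(gene_id, strand)]
    concordant: bool
    notes: list[str]


def compare_gene_order(
    gene_ids: list[str],
    assemblies: list[tuple[str, list[AnchorHit]]],
    region: str = "region",
    strict_absence: bool = False,
) -> OrderComparison:
    """Compare the order and orientation of a reference gene run across donors.

    An assembly is concordant when its present genes appear in the reference
    order with uniform '+' relative strand, or in fully reversed order with
    uniform '-' strand (a global flip of the whole region).  Absent genes are
    noted; they only break concordance when ``strict_absence`` is set.
    """
    ref_rank = {g: i for i, g in enumerate(gene_ids)}
    orders: dict[str, list[tuple[str, str]]] = {}
    notes: list[str] = []
    concordant = True
    for asm_id, hits in assemblies:
        relevant = [h for h in hits if h.gene_id in ref_rank]
        present = {h.gene_id for h in relevant}
        absent = [g for g in gene_ids if g not in present]
        if absent:
            notes.append(f"{asm_id}: absent {','.join(absent)}")
            if strict_absence:
                concordant = False
        if not relevant:
            orders[asm_id] = []
            continue
        seqs = {h.donor_seq_id for h in relevant}
        if len(seqs) > 1:
            notes.append(f"{asm_id}: genes split across {len(seqs)} sequences")
            concordant = False
        relevant.sort(key=lambda h: (h.donor_seq_id, h.start))
        observed = [(h.gene_id, h.strand) for h in relevant]
        orders[asm_id] = observed
        expected_fwd = sorted(present, key=lambda g: ref_rank[g])
        obs_ids = [g for g, _ in observed]
        strands = {s for _, s in observed}
        fwd_ok = obs_ids == expected_fwd and strands <= {"+"}
        rev_ok = obs_ids == expected_fwd[::-1] and strands <= {"-"}
        if not (fwd_ok or rev_ok):
            pair = _first_inversion(obs_ids, ref_rank)
            if pair:
                notes.append(f"{asm_id}: inverted pair {pair[0]},{pair[1]}")
            else:
                notes.append(f"{asm_id}: order/orientation discordant")
            concordant = False
    return OrderComparison(region=region, orders=orders, concordant=concordant, notes=notes)


def _first_inversion(obs: list[str], rank: dict[str, int]) -> tuple[str, str] | None:
    for a, b in zip(obs, obs[1:]):
        if rank[a] > rank[b]:
            return a, b
    return None
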