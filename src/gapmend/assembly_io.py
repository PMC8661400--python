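"""Readers and writers for the formats the curation pipeline touches.

All coordinates are 0-based half-open internally.  The only places where
1-based inclusive coordinates exist are the GFF3 and depth-TSV file
boundaries; conversion happens exactly once, on read/write, so the rest of
the package never thinks about off-by-one.

Sequence records carry a *role* (``chromosome``, ``unplaced`` or
``unlocalized``) which drives which records are censused for gaps and which
are candidates for placement or redundancy removal.  Roles come from
configuration, not from accession-prefix heuristics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ROLES = ("chromosome", "unplaced", "unlocalized")

# Anything outside ACGTN (ambiguity codes, gap dashes...) is coerced to N on
# ingest: the gap census is defined on N-runs, and donors from different
# centers use different ambiguity dialects.
_NON_ACGTN = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqEntry:
    """One FASTA record with its curation role."""

    seq_id: str
    sequence: str
    role: str = "chromosome"
    associated_chromosome: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.seq_id!r}")
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.seq_id!r}")
        if self.role == "unlocalized" and self.associated_chromosome is None:
            raise ValueError(
                f"unlocalized record {self.seq_id!r} needs an associated chromosome"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An ordered collection of sequence records with unique ids."""

    records: list[SeqEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.seq_id in seen:
                raise ValueError(f"duplicate sequence id {rec.seq_id!r}")
            seen.add(rec.seq_id)
        self._by_id = {rec.seq_id: rec for rec in self.records}

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __getitem__(self, seq_id: str) -> SeqEntry:
        return self._by_id[seq_id]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def seq_ids(self) -> list[str]:
        return [rec.seq_id for rec in self.records]

    def sequence(self, seq_id: str) -> str:
        return self._by_id[seq_id].sequence

    def length(self, seq_id: str) -> int:
        return len(self._by_id[seq_id].sequence)

    def chromosomes(self) -> list[SeqEntry]:
        return [r for r in self.records if r.role == "chromosome"]

    def scaffolds(self) -> list[SeqEntry]:
        return [r for r in self.records if r.role != "chromosome"]

    def with_record(self, entry: SeqEntry) -> "Assembly":
        return Assembly(self.records + [entry])

    def subset(self, seq_ids: Iterable[str]) -> "Assembly":
        wanted = set(seq_ids)
        return Assembly([r for r in self.records if r.seq_id in wanted])


@dataclass(frozen=True, order=True)
class GeneModel:
    """A gene interval used as a synteny anchor (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    gene_id: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start

    def sequence(self, assembly: Assembly) -> str:
        return assembly.sequence(self.seq_id)[self.start : self.end]


class DepthTrack:
    """Dense per-base read depth, one non-negative integer vector per sequence."""

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        self.vectors = {k: np.asarray(v, dtype=np.int64) for k, v in vectors.items()}
        for seq_id, vec in self.vectors.items():
            if (vec < 0).any():
                raise ValueError(f"negative depth in track for {seq_id!r}")

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.vectors

    def __getitem__(self, seq_id: str) -> np.ndarray:
        return self.vectors[seq_id]


def _normalize_sequence(raw: str, seq_id: str) -> str:
    seq = raw.upper()
    coerced = len(_NON_ACGTN.findall(seq))
    if coerced:
        logger.info("record %s: coerced %d non-ACGTN bases to N", seq_id, coerced)
        seq = _NON_ACGTN.sub("N", seq)
    return seq


def read_fasta(
    path: str | Path,
    roles: Mapping[str, str] | None = None,
    associations: Mapping[str, str] | None = None,
    default_role: str = "chromosome",
) -> Assembly:
    """Read a FASTA file into an :class:`Assembly`.

    Parameters
    ----------
    roles
        Optional per-record role override (seq_id -> role).  Records absent
        from the mapping get ``default_role``.
    associations
        seq_id -> chromosome id, required for records given the
        ``unlocalized`` role.
    """
    path = Path(path)
    roles = roles or {}
    associations = associations or {}
    records: list[SeqEntry] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SeqEntry(
                seq_id=rec.id,
                sequence=_normalize_sequence(str(rec.seq), rec.id),
                role=roles.get(rec.id, default_role),
                associated_chromosome=associations.get(rec.id),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Assembly(records)


def write_fasta(assembly: Assembly, path: str | Path, line_width: int = 80) -> Path:
    """Write an assembly as wrapped multi-record FASTA, in record order."""
    if line_width < 1:
        raise ValueError("line_width must be positive")
    path = Path(path)
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(
            SeqRecord(Seq(rec.sequence), id=rec.seq_id, description="")
            for rec in assembly
        )
    return path


_GFF_COLUMNS = [
    "seq_id", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _attribute(attrs: str, key: str) -> str | None:
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if chunk.startswith(key + "="):
            return chunk[len(key) + 1 :]
    return None


def read_gff3(
    path: str | Path,
    feature_type: str = "gene",
    id_attribute: str = "ID",
) -> list[GeneModel]:
    """Read gene rows from a GFF3 file, converting to 0-based half-open.

    Only rows of ``feature_type`` are retained.  File coordinates are 1-based
    inclusive; the returned intervals satisfy end - start == file span.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=_GFF_COLUMNS,
        header=None,
        dtype=str,
        keep_default_na=False,
    )
    if frame.empty:
        return []
    # line numbers for error messages: account for comment/header lines
    line_no = _gff_line_numbers(path, len(frame))
    genes: list[GeneModel] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        if row.type != feature_type:
            continue
        start_1, end_1 = int(row.start), int(row.end)
        if start_1 > end_1:
            raise ValueError(
                f"{path}:{line_no[idx]}: start {start_1} > end {end_1}"
            )
        gene_id = _attribute(row.attributes, id_attribute)
        if gene_id is None:
            raise ValueError(
                f"{path}:{line_no[idx]}: missing {id_attribute}= attribute"
            )
        genes.append(
            GeneModel(
                seq_id=row.seq_id,
                start=start_1 - 1,
                end=end_1,
                gene_id=gene_id,
                strand=row.strand if row.strand in ("+", "-") else "+",
            )
        )
    _check_unique_gene_ids(genes)
    return genes


def _gff_line_numbers(path: Path, n_rows: int) -> list[int]:
    numbers = []
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            numbers.append(i)
    return numbers[:n_rows] + [0] * max(0, n_rows - len(numbers))


def _check_unique_gene_ids(genes: list[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id!r} in annotation")
        seen.add(g.gene_id)


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "gapmend") -> Path:
    """Write gene models as GFF3 (converting back to 1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for g in genes:
            handle.write(
                f"{g.seq_id}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
    return path


def read_depth(
    path: str | Path,
    lengths: Mapping[str, int],
) -> DepthTrack:
    """Read a 3-column depth TSV (seq, 1-based pos, depth) into dense vectors.

    ``lengths`` declares the sequences the track covers; positions absent
    from the file get depth 0 (``samtools depth`` without ``-a`` omits them).
    """
    path = Path(path)
    vectors = {seq_id: np.zeros(n, dtype=np.int64) for seq_id, n in lengths.items()}
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["seq", "pos", "depth"], dtype=str,
            keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return DepthTrack(vectors)
    if frame.empty:
        return DepthTrack(vectors)
    for col in ("pos", "depth"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}:{line}: non-integer {col} value {frame[col][line - 1]!r}")
        frame[col] = numeric.astype(np.int64)
    for seq_id, group in frame.groupby("seq", sort=False):
        if seq_id not in vectors:
            logger.warning("depth track %s: unknown sequence %s skipped", path, seq_id)
            continue
        pos = group["pos"].to_numpy() - 1
        if (pos < 0).any() or (pos >= len(vectors[seq_id])).any():
            raise ValueError(f"{path}: position out of bounds for {seq_id!r}")
        vectors[seq_id][pos] = group["depth"].to_numpy()
    return DepthTrack(vectors)


def write_depth(track: DepthTrack, path: str | Path) -> Path:
    """Write a depth track as the 3-column TSV emitted by ``samtools depth -a``."""
    path = Path(path)
    with open(path, "w") as handle:
        for seq_id, vec in track.vectors.items():
            frame = pd.DataFrame(
                {"seq": seq_id, "pos": np.arange(1, len(vec) + 1), "depth": vec}
            )
            frame.to_csv(handle, sep="\t", header=False, index=False)
    return path


def relabel(entry: SeqEntry, new_id: str) -> SeqEntry:
    return replace(entry, seq_id=new_id)
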