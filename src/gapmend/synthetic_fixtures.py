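"""Seeded synthetic truth sets for exercising the whole curation pipeline.

The generator builds a *truth* genome — chromosomes with telomeric repeat
arrays at both ends, a catalog of gene-length unique segments, and tandem
repeat arrays planted around future gap sites (real assembly gaps sit in
repeat-enriched regions, and the repeats are what make flank validation a
meaningful test) — and then degrades it into the *reference* under test:

* planted gaps: stretches of truth sequence replaced by N-runs, mixing
  placeholder lengths (25/200 bp) with estimated-size runs, some inside gene
  bodies, one at a chromosome start with no upstream gene (unclosable by the
  anchored method) and one whose flanking anchor gene is deleted from every
  donor (unclosable in practice);
* truncated distal telomeres on chosen chromosome ends;
* unplaced scaffolds: copies of sequence from inside replaced regions
  (redundant after curation) and novel random sequence (must be retained).

Donor assemblies are the truth genome mutated at stated substitution/indel
rates with optional local inversions; depth tracks are per-base Poisson
draws with forced-low dropout intervals.  Every planted feature is recorded
in a manifest with exact coordinates in both the truth and the degraded
frame, so tests can check recovery rather than plausibility.  All output is
a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .assembly_io import (
    Assembly, DepthTrack, GeneModel, SeqEntry, revcomp,
    write_depth, write_fasta, write_gff3,
)
from .splice_editor import SpliceEvent, apply_splices

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


@dataclass
class DonorSpec:
    name: str
    source_class: str = "alternative"  # reassembly | alternative
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    inversions: list[tuple[str, int, int]] = field(default_factory=list)
    drop_genes: list[str] = field(default_factory=list)


@dataclass
class GapPlan:
    chrom: int
    kind: str  # intergenic | within_gene | boundary
    gap_len: int
    truth_len: int
    slot: int = 0  # gene index: after gene `slot` (intergenic) or inside gene `slot`
    closable: bool = True
    absent_gene: bool = False  # delete the upstream anchor gene from all donors


@dataclass
class SyntheticConfig:
    n_chromosomes: int = 3
    chromosome_length: int = 500_000
    genes_per_chromosome: int = 50
    gene_length: tuple[int, int] = (1500, 3000)
    left_telomere_len: int = 1500
    right_telomere_len: tuple[int, int] = (3000, 6000)
    repeat_motif_len: tuple[int, int] = (5, 50)
    gap_plans: list[GapPlan] = field(default_factory=list)
    telomere_truncations: list[tuple[int, str]] = field(default_factory=list)
    telomere_keep: int = 2000  # reference bases kept past the last gene after truncation
    redundant_scaffolds: list[int] = field(default_factory=list)  # indices into gap_plans
    novel_scaffolds: int = 2
    novel_scaffold_len: int = 5000
    donors: list[DonorSpec] = field(default_factory=list)
    depth_mean: float = 30.0
    dropout_per_donor: int = 2
    dropout_len: int = 5000
    dropout_mean: float = 1.0


def default_config() -> SyntheticConfig:
    """The standard study conditions: 3 chromosomes x ~500 kb, 150 genes,
    12 planted gaps (10 closable), 2 truncated distal telomeres, 3 redundant
    + 2 novel scaffolds, re-assembly donors at divergence 0 and alternative
    donors at 1% substitution divergence."""
    plans = [
        GapPlan(0, "intergenic", 25, 600, slot=10),
        GapPlan(0, "intergenic", 2000, 2000, slot=20),
        GapPlan(0, "within_gene", 200, 500, slot=30),
        GapPlan(0, "boundary", 1500, 1500, closable=False),
        GapPlan(1, "intergenic", 5000, 5000, slot=8),
        GapPlan(1, "within_gene", 25, 300, slot=18),
        GapPlan(1, "intergenic", 200, 1000, slot=28),
        GapPlan(1, "intergenic", 25, 400, slot=38, closable=False, absent_gene=True),
        GapPlan(2, "intergenic", 3000, 3000, slot=12),
        GapPlan(2, "within_gene", 200, 800, slot=22),
        GapPlan(2, "intergenic", 25, 400, slot=32),
        GapPlan(2, "intergenic", 1000, 1000, slot=42),
    ]
    donors = [
        DonorSpec("reFlye", "reassembly", sub_rate=0.0),
        DonorSpec("reND", "reassembly", sub_rate=0.0),
        DonorSpec("altA", "alternative", sub_rate=0.01),
        DonorSpec("altB", "alternative", sub_rate=0.01),
    ]
    return SyntheticConfig(
        gap_plans=plans,
        telomere_truncations=[(1, "right"), (2, "right")],
        redundant_scaffolds=[1, 4, 8],
        donors=donors,
    )


@dataclass
class PlantedGap:
    gap_index: int
    seq_id: str
    start: int  # degraded-reference coordinates of the N-run
    end: int
    gap_len: int
    kind: str
    gap_class: str
    closable: bool
    truth_interval: tuple[int, int]
    truth_replaced_interval: tuple[int, int]  # anchor-to-anchor span in truth coords


@dataclass
class SyntheticTruth:
    seed: int
    config: SyntheticConfig
    truth: Assembly
    reference: Assembly  # degraded chromosomes + scaffolds
    genes: list[GeneModel]  # reference (degraded) frame
    truth_genes: list[GeneModel]
    donors: dict[str, Assembly]
    donor_classes: dict[str, str]
    depth: dict[str, DepthTrack]
    planted_gaps: list[PlantedGap]
    telomere_truncations: list[dict]
    scaffold_truth: dict[str, str]  # scaffold id -> "redundant" | "novel"
    dropped_gene: str | None


def _build_chromosome(rng, cfg: SyntheticConfig, chrom_idx: int):
    """Assemble one truth chromosome; returns (sequence, genes, landmarks)."""
    seq_id = f"chr{chrom_idx + 1}"
    plans = [p for p in cfg.gap_plans if p.chrom == chrom_idx]
    by_slot_inter = {p.slot: p for p in plans if p.kind == "intergenic"}
    by_slot_within = {p.slot: p for p in plans if p.kind == "within_gene"}
    boundary = next((p for p in plans if p.kind == "boundary"), None)

    n_genes = cfg.genes_per_chromosome
    avg_gene = sum(cfg.gene_length) / 2
    right_tel = 5 * int(rng.integers(*[v // 5 for v in cfg.right_telomere_len]))
    budget = (
        cfg.chromosome_length - cfg.left_telomere_len - right_tel
        - 2500 - n_genes * avg_gene - 2000
    )
    base_spacing = max(1500, int(budget / max(1, n_genes - 1)))

    parts: list[str] = []
    pos = 0
    genes: list[GeneModel] = []
    gap_content: dict[int, tuple[int, int]] = {}  # plan id -> truth interval of content
    repeat_arrays: list[str] = []

    def emit(s: str):
        nonlocal pos
        parts.append(s)
        pos += len(s)

    emit("CCTAA" * (cfg.left_telomere_len // 5))
    # chromosome-start margin, optionally hosting the boundary gap content
    if boundary is not None:
        emit(_random_seq(rng, 300))
        lo = pos
        emit(_gap_region_seq(rng, cfg, boundary.truth_len, repeat_arrays))
        gap_content[id(boundary)] = (lo, pos)
        emit(_random_seq(rng, 900))
    else:
        emit(_random_seq(rng, 2500))

    for i in range(n_genes):
        if i > 0:
            plan = by_slot_inter.get(i - 1)
            if plan is not None:
                pad = max(1500, (base_spacing - plan.truth_len) // 2)
                emit(_random_seq(rng, pad))
                lo = pos
                emit(_gap_region_seq(rng, cfg, plan.truth_len, repeat_arrays))
                gap_content[id(plan)] = (lo, pos)
                emit(_random_seq(rng, pad))
            else:
                emit(_random_seq(rng, base_spacing + int(rng.integers(-300, 300))))
        wplan = by_slot_within.get(i)
        if wplan is not None:
            inner = max(800, (max(2500, wplan.truth_len + 1600) - wplan.truth_len) // 2)
            g_lo = pos
            emit(_random_seq(rng, inner))
            lo = pos
            emit(_gap_region_seq(rng, cfg, wplan.truth_len, repeat_arrays))
            gap_content[id(wplan)] = (lo, pos)
            emit(_random_seq(rng, inner))
            g_hi = pos
        else:
            g_lo = pos
            emit(_random_seq(rng, int(rng.integers(*cfg.gene_length))))
            g_hi = pos
        genes.append(
            GeneModel(
                seq_id=seq_id, start=g_lo, end=g_hi,
                gene_id=f"G{chrom_idx + 1:02d}{i + 1:03d}",
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    emit(_random_seq(rng, 2000))
    emit("TTAGG" * (right_tel // 5))
    return seq_id, "".join(parts), genes, gap_content, repeat_arrays


def _gap_region_seq(rng, cfg: SyntheticConfig, length: int, repeat_arrays: list[str]) -> str:
    """Truth content destined to become a gap: random sequence with a
    centered tandem-repeat array when there is room."""
    if length < 400:
        return _random_seq(rng, length)
    motif = _random_seq(rng, int(rng.integers(*cfg.repeat_motif_len)))
    array_len = min(1500, length // 2)
    array = (motif * (array_len // len(motif) + 1))[:array_len]
    repeat_arrays.append(array)
    rest = length - array_len
    left = rest // 2
    return _random_seq(rng, left) + array + _random_seq(rng, rest - left)


def mutate_donor(
    truth: Assembly,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    inversions: list[tuple[str, int, int]] | None = None,
    seed: int | np.random.Generator = 0,
) -> Assembly:
    """Point-mutate a genome: inversions first (truth coordinates), then
    substitutions and small (1-3 bp) indels at the given per-base rates."""
    if not (0 <= sub_rate <= 0.05 and 0 <= indel_rate <= 0.05):
        raise ValueError("rates must be in [0, 0.05]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inversions = inversions or []
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for seq_id, lo, hi in inversions:
        by_seq.setdefault(seq_id, []).append((lo, hi))
    for seq_id, ivs in by_seq.items():
        ivs.sort()
        for (a1, b1), (a2, _) in zip(ivs, ivs[1:]):
            if b1 > a2:
                raise ValueError(f"overlapping inversions on {seq_id}")
    records = []
    for rec in truth:
        seq = rec.sequence
        for lo, hi in sorted(by_seq.get(rec.seq_id, []), reverse=True):
            seq = seq[:lo] + revcomp(seq[lo:hi]) + seq[hi:]
        b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        if sub_rate > 0:
            enc = np.full(256, -1, dtype=np.int8)
            for base, v in zip(b"ACGT", range(4)):
                enc[base] = v
            code = enc[b]
            mask = (rng.random(len(b)) < sub_rate) & (code >= 0)
            shift = rng.integers(1, 4, size=int(mask.sum()))
            b[mask] = _BASES[(code[mask] + shift) % 4]
        seq = b.tobytes().decode("ascii")
        if indel_rate > 0:
            n_indels = rng.poisson(indel_rate * len(seq))
            positions = np.sort(rng.integers(100, max(101, len(seq) - 100), size=n_indels))[::-1]
            for p in positions:
                size = int(rng.integers(1, 4))
                if rng.random() < 0.5:
                    seq = seq[:p] + seq[p + size :]
                else:
                    seq = seq[:p] + _random_seq(rng, size) + seq[p:]
        records.append(SeqEntry(rec.seq_id, seq, rec.role, rec.associated_chromosome))
    return Assembly(records)


def simulate_truth(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Build a complete in-memory truth set (see module docstring)."""
    cfg = config or default_config()
    rng = np.random.default_rng(seed)

    truth_records: list[SeqEntry] = []
    truth_genes: list[GeneModel] = []
    gap_content_all: dict[int, tuple[str, tuple[int, int]]] = {}
    arrays_by_chrom: list[list[str]] = []
    for c in range(cfg.n_chromosomes):
        seq_id, seq, genes, gap_content, arrays = _build_chromosome(rng, cfg, c)
        truth_records.append(SeqEntry(seq_id, seq))
        truth_genes.extend(genes)
        for pid, iv in gap_content.items():
            gap_content_all[pid] = (seq_id, iv)
        arrays_by_chrom.append(arrays)
    # duplicate one repeat array into another chromosome's gene-free tail as
    # a paralogy decoy (past the last gene, so no coordinates need shifting)
    if cfg.n_chromosomes > 1 and arrays_by_chrom[0]:
        decoy = arrays_by_chrom[0][0]
        rec = truth_records[1]
        last_gene_end = max(g.end for g in truth_genes if g.seq_id == rec.seq_id)
        insert_at = last_gene_end + 500
        truth_records[1] = SeqEntry(
            rec.seq_id,
            rec.sequence[:insert_at] + decoy + rec.sequence[insert_at:],
            rec.role,
        )
    truth = Assembly(truth_records)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in truth_genes:
        genes_by_chrom.setdefault(g.seq_id, []).append(g)

    # --- degrade: plant N-runs and truncate telomeres ---------------------
    events: list[SpliceEvent] = []
    plan_events: dict[int, SpliceEvent] = {}
    for idx, plan in enumerate(cfg.gap_plans):
        seq_id, (lo, hi) = gap_content_all[id(plan)]
        ev = SpliceEvent(
            event_id=f"plant_gap{idx}", seq_id=seq_id,
            replaced_interval=(lo, hi), replacement="N" * plan.gap_len,
            event_type="gap_close",
        )
        events.append(ev)
        plan_events[idx] = ev
    truncations: list[dict] = []
    for chrom_idx, end in cfg.telomere_truncations:
        seq_id = f"chr{chrom_idx + 1}"
        length = truth.length(seq_id)
        if end == "right":
            last = max(genes_by_chrom[seq_id], key=lambda g: g.end)
            cut_from = last.end + cfg.telomere_keep
            iv = (cut_from, length)
        else:
            first = min(genes_by_chrom[seq_id], key=lambda g: g.start)
            iv = (0, max(0, first.start - cfg.telomere_keep))
        events.append(
            SpliceEvent(
                event_id=f"truncate_{seq_id}_{end}", seq_id=seq_id,
                replaced_interval=iv, replacement="", event_type="telomere_add",
            )
        )
        truncations.append(
            {"seq_id": seq_id, "end": end, "removed_len": iv[1] - iv[0]}
        )
    degraded, chain = apply_splices(truth, events, prefix="")

    # reference-frame gene coordinates (gene bodies never contain an edit
    # boundary, so both ends lift cleanly)
    ref_genes = [
        GeneModel(
            g.seq_id,
            chain.lift_position(g.seq_id, g.start),
            chain.lift_position(g.seq_id, g.end - 1) + 1,
            g.gene_id,
            g.strand,
        )
        for g in truth_genes
    ]

    planted: list[PlantedGap] = []
    gene_by_id = {g.gene_id: g for g in truth_genes}
    for idx, plan in enumerate(cfg.gap_plans):
        ev = plan_events[idx]
        spans = {e.event_id: (lo, hi) for lo, hi, e in chain.inserted_spans(ev.seq_id)}
        n_lo, n_hi = spans[ev.event_id]
        planted.append(
            PlantedGap(
                gap_index=idx, seq_id=ev.seq_id, start=n_lo, end=n_hi,
                gap_len=plan.gap_len, kind=plan.kind,
                gap_class="arbitrary" if plan.gap_len in (25, 200) else "estimated",
                closable=plan.closable,
                truth_interval=ev.replaced_interval,
                truth_replaced_interval=_truth_replaced_span(
                    plan, ev, genes_by_chrom[ev.seq_id]
                ),
            )
        )

    # the gap marked absent_gene loses its upstream anchor gene in every donor
    dropped_gene: str | None = None
    for plan in cfg.gap_plans:
        if plan.absent_gene:
            seq_id, (lo, _) = gap_content_all[id(plan)]
            upstream = max(
                (g for g in genes_by_chrom[seq_id] if g.end <= lo),
                key=lambda g: g.end,
            )
            dropped_gene = upstream.gene_id

    donors: dict[str, Assembly] = {}
    donor_classes: dict[str, str] = {}
    for spec in cfg.donors:
        source = truth
        drop = list(spec.drop_genes) + ([dropped_gene] if dropped_gene else [])
        if drop:
            del_events = [
                SpliceEvent(
                    event_id=f"drop_{gid}", seq_id=gene_by_id[gid].seq_id,
                    replaced_interval=(gene_by_id[gid].start, gene_by_id[gid].end),
                    replacement="",
                )
                for gid in drop
            ]
            source, _ = apply_splices(source, del_events, prefix="")
        donors[spec.name] = mutate_donor(
            source, spec.sub_rate, spec.indel_rate, spec.inversions, seed=rng
        )
        donor_classes[spec.name] = spec.source_class

    # --- scaffolds --------------------------------------------------------
    scaffold_records: list[SeqEntry] = []
    scaffold_truth: dict[str, str] = {}
    for i, plan_idx in enumerate(cfg.redundant_scaffolds):
        pg = planted[plan_idx]
        t_lo, t_hi = pg.truth_replaced_interval
        lo, hi = t_lo + 500, t_hi - 500
        if hi - lo < 1000:
            lo, hi = t_lo, t_hi
        sid = f"scaffold_red{i + 1}"
        scaffold_records.append(
            SeqEntry(sid, truth.sequence(pg.seq_id)[lo:hi], role="unplaced")
        )
        scaffold_truth[sid] = "redundant"
    for i in range(cfg.novel_scaffolds):
        sid = f"scaffold_nov{i + 1}"
        scaffold_records.append(
            SeqEntry(sid, _random_seq(rng, cfg.novel_scaffold_len), role="unplaced")
        )
        scaffold_truth[sid] = "novel"

    reference = Assembly(list(degraded.records) + scaffold_records)

    # --- depth tracks -----------------------------------------------------
    depth: dict[str, DepthTrack] = {}
    for name, asm in [("reference", reference)] + list(donors.items()):
        vectors = {}
        for rec in asm.chromosomes():
            vec = rng.poisson(cfg.depth_mean, size=len(rec.sequence))
            for _ in range(cfg.dropout_per_donor if name != "reference" else 0):
                at = int(rng.integers(0, max(1, len(vec) - cfg.dropout_len)))
                vec[at : at + cfg.dropout_len] = rng.poisson(
                    cfg.dropout_mean, size=min(cfg.dropout_len, len(vec) - at)
                )
            vectors[rec.seq_id] = vec
        depth[name] = DepthTrack(vectors)

    return SyntheticTruth(
        seed=seed, config=cfg, truth=truth, reference=reference,
        genes=ref_genes, truth_genes=truth_genes, donors=donors,
        donor_classes=donor_classes, depth=depth, planted_gaps=planted,
        telomere_truncations=truncations, scaffold_truth=scaffold_truth,
        dropped_gene=dropped_gene,
    )


def _truth_replaced_span(plan: GapPlan, ev: SpliceEvent, genes: list[GeneModel]) -> tuple[int, int]:
    """Anchor-to-anchor truth span the closing engine should restore."""
    lo, hi = ev.replaced_interval
    if plan.kind == "within_gene":
        gene = next(g for g in genes if g.start <= lo and hi <= g.end)
        return (gene.start, gene.end)
    ups = [g for g in genes if g.end <= lo]
    downs = [g for g in genes if g.start >= hi]
    up = max((g.end for g in ups), default=0)
    down = min((g.start for g in downs), default=hi)
    return (up, down)


def generate_truth_set(
    config: SyntheticConfig | None = None, seed: int = 0, out_dir: str | Path = "."
) -> dict[str, Path]:
    """Materialize a truth set as files: truth/reference/donor FASTAs, GFF3
    gene annotation, per-assembly depth TSVs, scaffold FASTA and a JSON
    manifest of every planted feature."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts = simulate_truth(config, seed)
    paths: dict[str, Path] = {}
    paths["truth"] = write_fasta(ts.truth, out / "truth.fasta")
    paths["reference"] = write_fasta(ts.reference, out / "reference.fasta")
    paths["genes"] = write_gff3(ts.genes, out / "genes.gff3")
    scaffolds = ts.reference.scaffolds()
    if scaffolds:
        paths["scaffolds"] = write_fasta(Assembly(scaffolds), out / "scaffolds.fasta")
        paths["scaffold_list"] = out / "scaffolds.tsv"
        paths["scaffold_list"].write_text(
            "".join(
                f"{r.seq_id}\t{r.associated_chromosome or ''}\n" for r in scaffolds
            )
        )
    for name, asm in ts.donors.items():
        paths[f"donor_{name}"] = write_fasta(asm, out / f"donor_{name}.fasta")
    for name, track in ts.depth.items():
        paths[f"depth_{name}"] = write_depth(track, out / f"depth_{name}.tsv")
    manifest = {
        "seed": ts.seed,
        "planted_gaps": [asdict(p) for p in ts.planted_gaps],
        "telomere_truncations": ts.telomere_truncations,
        "scaffold_truth": ts.scaffold_truth,
        "dropped_gene": ts.dropped_gene,
        "donor_classes": ts.donor_classes,
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths
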