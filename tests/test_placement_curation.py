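import numpy as np
import pytest

from gapmend.assembly_io import Assembly, GeneModel, SeqEntry, revcomp
from gapmend.anchor_synteny import KmerAligner, anchor_gene
from gapmend.gap_census import assign_flanks, classify_gaps, find_gaps
from gapmend.placement_curation import (
    DuplicatedAnchorError, consensus_place_scaffold, detect_redundant,
    motif_coverage, recover_telomere, scan_telomeres,
)
from gapmend.splice_editor import SpliceEvent, apply_splices

from conftest import random_assembly


def _rand(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestTelomereScan:
    def test_pure_repeat_is_present(self):
        asm = Assembly([SeqEntry("s", "TTAGG" * 200 + _rand(0, 11_000))])
        scan = scan_telomeres(asm)["s"]
        assert scan.densities[0] == 1.0
        assert scan.left_call == "present"
        assert scan.right_call == "absent"

    def test_random_sequence_is_absent(self):
        """Random ACGT carries ~5/4^5 expected motif coverage per position
        per motif; windowed density stays far below the 0.4 call floor."""
        seq = _rand(1, 10_000)
        scan = scan_telomeres(Assembly([SeqEntry("s", seq)]))["s"]
        covered = motif_coverage(seq)
        assert scan.densities.max() <= 0.02
        assert covered.mean() <= 0.02
        assert scan.left_call == scan.right_call == "absent"
        # densities agree with the brute-force coverage scan per window
        for i, d in enumerate(scan.densities):
            assert d == pytest.approx(covered[i * 1000 : (i + 1) * 1000].mean())

    def test_truncated_end_called_absent_only_there(self, small_truth):
        scans = scan_telomeres(small_truth.reference)
        trunc = {(t["seq_id"], t["end"]) for t in small_truth.telomere_truncations}
        for rec in small_truth.reference.chromosomes():
            scan = scans[rec.seq_id]
            for end in ("left", "right"):
                expected = "absent" if (rec.seq_id, end) in trunc else "present"
                assert scan.distal_call(end) == expected

    def test_revcomp_invariance_with_motif_swap(self):
        seq = "CCTAA" * 100 + _rand(2, 3750) + "TTAGG" * 150  # length % 1000 == 0
        rc = revcomp(seq)
        fwd = scan_telomeres(Assembly([SeqEntry("s", seq)]))["s"]
        rev = scan_telomeres(Assembly([SeqEntry("s", rc)]))["s"]
        assert np.allclose(fwd.densities, rev.densities[::-1])
        assert (fwd.left_call, fwd.right_call) == (rev.right_call, rev.left_call)


class TestRecoverTelomere:
    def test_exact_restoration_with_perfect_donor(self, small_truth):
        ts = small_truth
        trunc = ts.telomere_truncations[0]
        seq_id = trunc["seq_id"]
        rec = ts.reference[seq_id]
        donor = ts.donors["re0"]
        event = recover_telomere(
            rec, ts.genes, ts.reference, "re0", donor, KmerAligner(donor), end="right"
        )
        assert event is not None
        corrected, _ = apply_splices(ts.reference.subset([seq_id]), [event])
        # the chromosome still carries its planted gaps upstream; the graft
        # must restore the truth tail across the junction exactly
        n = event.inserted_length + 5000
        assert corrected.sequence("cor_" + seq_id)[-n:] == ts.truth.sequence(seq_id)[-n:]

    def test_distance_matches_donor_distance(self):
        """After grafting, the last-gene-to-end distance equals the donor's
        (the diagnostic the curation is driven by)."""
        L = 60_000
        truth_seq = _rand(5, L - 3000) + "TTAGG" * 600
        gene = GeneModel("c5", L - 20_481, L - 19_481, "last")
        truth = Assembly([SeqEntry("c5", truth_seq)])
        ref = Assembly([SeqEntry("c5", truth_seq[: gene.end + 7405])])
        event = recover_telomere(
            ref["c5"], [gene], ref, "d", truth, KmerAligner(truth), end="right"
        )
        assert event is not None
        assert event.replaced_interval == (gene.end, gene.end + 7405)
        assert event.inserted_length == 19_481
        corrected, _ = apply_splices(ref, [event])
        assert corrected.length("cor_c5") - gene.end == 19_481

    def test_telomeric_end_yields_no_proposal(self, small_truth):
        ts = small_truth
        intact = next(
            r for r in ts.reference.chromosomes()
            if not any(t["seq_id"] == r.seq_id for t in ts.telomere_truncations)
        )
        donor = ts.donors["re0"]
        assert recover_telomere(
            intact, ts.genes, ts.reference, "re0", donor, KmerAligner(donor), end="right"
        ) is None

    def test_duplicated_anchor_raises(self, small_truth):
        ts = small_truth
        trunc = ts.telomere_truncations[0]
        seq_id = trunc["seq_id"]
        rec = ts.reference[seq_id]
        anchor = max(
            (g for g in ts.genes if g.seq_id == seq_id), key=lambda g: g.end
        )
        base = ts.donors["re0"]
        dup_seq = base.sequence(seq_id) + _rand(9, 200) + anchor.sequence(ts.reference)
        donor = Assembly(
            [r if r.seq_id != seq_id else SeqEntry(seq_id, dup_seq) for r in base]
        )
        with pytest.raises(DuplicatedAnchorError):
            recover_telomere(
                rec, ts.genes, ts.reference, "dup", donor, KmerAligner(donor), end="right"
            )


@pytest.fixture(scope="module")
def placement_scene():
    """A scaffold excised from between two chromosome genes, plus three
    identical donors that retain the full region."""
    truth_seq = _rand(77, 40_000)
    A = GeneModel("chrP", 5000, 6000, "A")
    B_truth = (16_000, 17_000)
    scaffold_seq = truth_seq[9500:13_500]
    scaffold = SeqEntry("scafP", scaffold_seq, role="unplaced")
    scaffold_genes = [
        GeneModel("scafP", 500, 1500, "S1"),
        GeneModel("scafP", 2500, 3500, "S2"),
    ]
    truth = Assembly([SeqEntry("chrP", truth_seq)])
    donors = {f"d{i}": truth for i in (1, 2, 3)}
    return dict(
        truth_seq=truth_seq, A=A, B_truth=B_truth, scaffold=scaffold,
        scaffold_genes=scaffold_genes, donors=donors,
    )


def _scene_tables(scene, ref_assembly, ref_genes):
    aligners = {n: KmerAligner(a) for n, a in scene["donors"].items()}
    tables = {
        n: {
            g.gene_id: hit
            for g in ref_genes
            for status, hit in [anchor_gene(g, ref_assembly, n, al)]
            if status == "unique"
        }
        for n, al in aligners.items()
    }
    return aligners, tables


class TestConsensusPlacement:
    def _reference(self, scene, with_gap: bool):
        ts = scene["truth_seq"]
        if with_gap:
            chrom = ts[:9500] + "N" * 100 + ts[13_500:]
            b_lo = scene["B_truth"][0] - 4000 + 100
        else:
            chrom = ts[:9500] + ts[13_500:]
            b_lo = scene["B_truth"][0] - 4000
        ref = Assembly([SeqEntry("chrP", chrom), scene["scaffold"]])
        genes = [scene["A"], GeneModel("chrP", b_lo, b_lo + 1000, "B")]
        return ref, genes

    def test_three_of_three_donors_place(self, placement_scene):
        ref, genes = self._reference(placement_scene, with_gap=False)
        aligners, tables = _scene_tables(placement_scene, ref, genes)
        decision = consensus_place_scaffold(
            placement_scene["scaffold"], placement_scene["scaffold_genes"], ref,
            genes, tables, aligners, gaps=[], min_support=3,
        )
        assert decision.action == "place"
        assert decision.supporting_assemblies == 3
        assert decision.target_seq_id == "chrP"
        assert decision.target_interval == (6000, 12_000)
        assert decision.orientation == "+"

    def test_single_donor_insufficient(self, placement_scene):
        ref, genes = self._reference(placement_scene, with_gap=False)
        aligners, tables = _scene_tables(placement_scene, ref, genes)
        one = {"d1": aligners["d1"]}
        decision = consensus_place_scaffold(
            placement_scene["scaffold"], placement_scene["scaffold_genes"], ref,
            genes, {"d1": tables["d1"]}, one, gaps=[], min_support=3,
        )
        assert decision.action == "unresolved"
        assert any("insufficient support" in n for n in decision.notes)

    def test_consensus_over_gap_becomes_close_gap(self, placement_scene):
        ref, genes = self._reference(placement_scene, with_gap=True)
        gaps = assign_flanks(classify_gaps(find_gaps(ref)), genes)
        aligners, tables = _scene_tables(placement_scene, ref, genes)
        decision = consensus_place_scaffold(
            placement_scene["scaffold"], placement_scene["scaffold_genes"], ref,
            genes, tables, aligners, gaps=gaps, min_support=3,
        )
        assert decision.action == "close_gap"

    def test_no_markers_unresolved(self, placement_scene):
        ref, genes = self._reference(placement_scene, with_gap=False)
        decision = consensus_place_scaffold(
            placement_scene["scaffold"], [], ref, genes, {}, {}, min_support=3,
        )
        assert decision.action == "unresolved"
        assert "no_markers" in decision.notes

    def test_donor_order_permutation_invariance(self, placement_scene):
        ref, genes = self._reference(placement_scene, with_gap=False)
        aligners, tables = _scene_tables(placement_scene, ref, genes)
        results = []
        for order in (["d1", "d2", "d3"], ["d3", "d1", "d2"]):
            decision = consensus_place_scaffold(
                placement_scene["scaffold"], placement_scene["scaffold_genes"], ref,
                genes, {n: tables[n] for n in order},
                {n: aligners[n] for n in order}, gaps=[], min_support=3,
            )
            results.append(
                (decision.action, decision.target_interval, decision.orientation)
            )
        assert results[0] == results[1]


class TestRedundancy:
    @pytest.fixture()
    def corrected_scene(self):
        ref = random_assembly(31, {"chrR": 30_000})
        gcs = _rand(32, 4000)
        event = SpliceEvent("close_g", "chrR", (10_000, 12_000), gcs)
        corrected, chain = apply_splices(ref, [event])
        return ref, gcs, corrected, chain

    def test_scaffold_inside_gcs_is_redundant(self, corrected_scene):
        ref, gcs, corrected, chain = corrected_scene
        scaffold = SeqEntry("s1", gcs[500:3500], role="unplaced")
        decisions = detect_redundant([scaffold], corrected, chain)
        assert decisions[0].action == "redundant"

    def test_random_scaffold_retained(self, corrected_scene):
        ref, gcs, corrected, chain = corrected_scene
        scaffold = SeqEntry("s2", _rand(33, 3000), role="unplaced")
        decisions = detect_redundant([scaffold], corrected, chain)
        assert decisions[0].action == "retained"

    def test_good_alignment_outside_inserted_spans_retained(self, corrected_scene):
        ref, gcs, corrected, chain = corrected_scene
        scaffold = SeqEntry("s3", ref.sequence("chrR")[2000:5000], role="unplaced")
        decisions = detect_redundant([scaffold], corrected, chain)
        assert decisions[0].action == "retained"
        assert any("outside inserted spans" in n for n in decisions[0].notes)

    def test_exact_confusion_matrix_on_truth_set(self, small_truth, small_result):
        """Every planted redundant scaffold removed, nothing else removed."""
        flagged = {
            d.scaffold_id for d in small_result.redundancy if d.action == "redundant"
        }
        planted = {
            sid for sid, kind in small_truth.scaffold_truth.items() if kind == "redundant"
        }
        assert flagged == planted
        kept_ids = set(small_result.corrected.seq_ids)
        assert not planted & kept_ids
        novel = {
            sid for sid, kind in small_truth.scaffold_truth.items() if kind == "novel"
        }
        assert novel <= kept_ids
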