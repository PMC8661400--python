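import numpy as np
import pytest

from gapmend.assembly_io import Assembly, DepthTrack, GeneModel, SeqEntry, revcomp
from gapmend.anchor_synteny import AnchorHit, KmerAligner, map_gene_to_donor
from gapmend.gap_census import assign_flanks, classify_gaps, find_gaps
from gapmend.gcs_engine import (
    GCSCandidate, coverage_stats, extract_gcs, rank_candidates, validate_flanks,
)


def _rand(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="module")
def scenario():
    """A hand-built gap: truth genome, degraded reference, perfect donor."""
    truth_seq = _rand(42, 12_000)
    truth = Assembly([SeqEntry("chr", truth_seq)])
    # gap content [3000, 4500) replaced by N*25 in the reference
    ref_seq = truth_seq[:3000] + "N" * 25 + truth_seq[4500:]
    reference = Assembly([SeqEntry("chr", ref_seq)])
    up = GeneModel("chr", 2000, 2600, "up")
    down = GeneModel("chr", 3525, 4125, "down")  # truth [5000, 5600) shifted -1475
    gap = assign_flanks(classify_gaps(find_gaps(reference)), [up, down])[0]
    assert (gap.start, gap.end) == (3000, 3025)
    donor = truth
    aligner = KmerAligner(donor)
    up_hit = map_gene_to_donor(up, reference, donor, aligner, donor_id="d")
    down_hit = map_gene_to_donor(down, reference, donor, aligner, donor_id="d")
    return dict(
        truth_seq=truth_seq, reference=reference, donor=donor, gap=gap,
        up=up, down=down, up_hit=up_hit, down_hit=down_hit,
    )


class TestExtract:
    def test_perfect_donor_restores_truth_substring(self, scenario):
        s = scenario
        cand = extract_gcs(s["gap"], s["donor"], s["up_hit"], s["down_hit"], s["up"], s["down"])
        assert cand.status == "candidate"
        assert cand.sequence == s["truth_seq"][2600:5000]
        assert cand.replaced_ref_interval == (2600, 3525)

    def test_reverse_complement_donor_equivariance(self, scenario):
        s = scenario
        rc_donor = Assembly([SeqEntry("chr", revcomp(s["donor"].sequence("chr")))])
        aligner = KmerAligner(rc_donor)
        up_hit = map_gene_to_donor(s["up"], s["reference"], rc_donor, aligner, donor_id="d")
        down_hit = map_gene_to_donor(s["down"], s["reference"], rc_donor, aligner, donor_id="d")
        assert up_hit.strand == down_hit.strand == "-"
        cand = extract_gcs(s["gap"], rc_donor, up_hit, down_hit, s["up"], s["down"])
        forward = extract_gcs(
            s["gap"], s["donor"], s["up_hit"], s["down_hit"], s["up"], s["down"]
        )
        assert cand.sequence == forward.sequence

    def test_split_anchor_rejected(self, scenario):
        s = scenario
        far = AnchorHit("down", "d", "other_seq", 100, 700, "+", 1.0, 1.0)
        cand = extract_gcs(s["gap"], s["donor"], s["up_hit"], far, s["up"], s["down"])
        assert (cand.status, cand.reason) == ("rejected", "split_anchor")

    def test_out_of_order_anchors_rejected(self, scenario):
        s = scenario
        before = AnchorHit("down", "d", "chr", 100, 700, "+", 1.0, 1.0)
        cand = extract_gcs(s["gap"], s["donor"], s["up_hit"], before, s["up"], s["down"])
        assert (cand.status, cand.reason) == ("rejected", "order_conflict")

    def test_gapped_donor_span_rejected(self, scenario):
        s = scenario
        t = s["donor"].sequence("chr")
        gapped = Assembly([SeqEntry("chr", t[:3700] + "N" * 50 + t[3700:])])
        up_hit = s["up_hit"]
        down_hit = AnchorHit("down", "d", "chr", 5050, 5650, "+", 1.0, 1.0)
        cand = extract_gcs(s["gap"], gapped, up_hit, down_hit, s["up"], s["down"])
        assert (cand.status, cand.reason) == ("rejected", "donor_gapped")

    def test_within_gene_replaces_whole_gene(self, scenario):
        """A gap inside a gene swaps in the donor's complete gene body."""
        s = scenario
        truth_seq = s["truth_seq"]
        # a gene [2000, 5600) containing the gap; single whole-gene anchor
        gene = GeneModel("chr", 2000, 4125, "big")
        hit = AnchorHit("big", "d", "chr", 2000, 5600, "+", 1.0, 1.0)
        gap = s["gap"]
        gap.within_gene = "big"
        cand = extract_gcs(gap, s["donor"], hit, hit, gene, gene)
        gap.within_gene = None
        assert cand.whole_gene
        assert cand.sequence == truth_seq[2000:5600]
        assert cand.replaced_ref_interval == (2000, 4125)


class TestValidateFlanks:
    def _candidate(self, scenario):
        s = scenario
        return extract_gcs(s["gap"], s["donor"], s["up_hit"], s["down_hit"], s["up"], s["down"])

    def test_perfect_donor_validates(self, scenario):
        cand = validate_flanks(self._candidate(scenario), scenario["reference"], scenario["donor"])
        assert cand.status == "validated"
        assert cand.upstream_flank_identity == 1.0
        assert cand.downstream_flank_identity == 1.0

    @pytest.mark.parametrize("n_subs,expect", [(5, "validated"), (6, "rejected")])
    def test_flank_identity_threshold(self, scenario, n_subs, expect):
        """5 substitutions in a 100 bp flank sit exactly at the 0.95 floor;
        6 fall below it (Hamming-count oracle on the planted flank)."""
        s = scenario
        donor_seq = list(s["donor"].sequence("chr"))
        # GCS starts at donor 2600; its upstream flank is [2500, 2600)
        for i in range(n_subs):
            pos = 2505 + 15 * i
            donor_seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[donor_seq[pos]]
        mutated = Assembly([SeqEntry("chr", "".join(donor_seq))])
        cand = extract_gcs(s["gap"], mutated, s["up_hit"], s["down_hit"], s["up"], s["down"])
        cand = validate_flanks(cand, s["reference"], mutated)
        assert cand.status == expect
        assert cand.upstream_flank_identity == pytest.approx(1 - n_subs / 100)

    def test_decoy_from_wrong_locus_rejected(self, scenario):
        """A candidate cut from a different locus has foreign flanks."""
        s = scenario
        up_hit = AnchorHit("up", "d", "chr", 6900, 7500, "+", 1.0, 1.0)
        down_hit = AnchorHit("down", "d", "chr", 9300, 9900, "+", 1.0, 1.0)
        cand = extract_gcs(s["gap"], s["donor"], up_hit, down_hit, s["up"], s["down"])
        cand = validate_flanks(cand, s["reference"], s["donor"])
        assert (cand.status, cand.reason) == ("rejected", "flank_mismatch")


class TestCoverageStats:
    def test_constant_depth(self):
        track = DepthTrack({"s": np.full(100, 10)})
        assert coverage_stats(track, "s", (10, 60)) == (10.0, 0.0)

    def test_two_point(self):
        track = DepthTrack({"s": np.array([0, 10])})
        mean, cv = coverage_stats(track, "s", (0, 2))
        assert (mean, cv) == (5.0, 1.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        vec = rng.integers(0, 60, 500)
        track = DepthTrack({"s": vec})
        mean, cv = coverage_stats(track, "s", (100, 400))
        window = vec[100:400]
        assert mean == pytest.approx(sum(window) / 300)
        manual_sd = (sum((x - mean) ** 2 for x in window) / 300) ** 0.5
        assert cv == pytest.approx(manual_sd / mean)

    def test_empty_interval_error(self):
        track = DepthTrack({"s": np.ones(10, dtype=int)})
        with pytest.raises(ValueError):
            coverage_stats(track, "s", (5, 5))


def _cand(donor, source_class, mean=None, cv=None, size=100, status="validated"):
    return GCSCandidate(
        gap_id="g", donor_id=donor, source_class=source_class, donor_seq_id="c",
        donor_interval=(0, size), strand="+", sequence="A" * size,
        ref_seq_id="chr", replaced_ref_interval=(0, 50),
        depth_mean=mean, depth_cv=cv, status=status,
    )


class TestRanking:
    def test_reassembly_beats_alternative_despite_depth(self):
        re_c = _cand("re", "reassembly", mean=20)
        alt = _cand("alt", "alternative", mean=30)
        assert rank_candidates([alt, re_c]).donor_id == "re"

    def test_higher_mean_wins_within_class(self):
        a = _cand("a", "alternative", mean=30)
        b = _cand("b", "alternative", mean=20)
        assert rank_candidates([b, a]).donor_id == "a"

    def test_cv_then_length_then_name_tiebreaks(self):
        a = _cand("a", "alternative", mean=30, cv=0.5)
        b = _cand("b", "alternative", mean=30, cv=0.2)
        assert rank_candidates([a, b]).donor_id == "b"
        c = _cand("c", "alternative", mean=30, cv=0.2, size=50)
        assert rank_candidates([_cand("a", "alternative", mean=30, cv=0.2), c]).donor_id == "c"

    def test_no_validated_gives_none(self):
        rejected = _cand("a", "alternative", status="rejected")
        assert rank_candidates([rejected]) is None
        assert rank_candidates([]) is None

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        base = [
            _cand("a", "alternative", mean=30, cv=0.2),
            _cand("b", "reassembly", mean=5, cv=0.9),
            _cand("c", "alternative", mean=40, cv=0.1),
            _cand("d", "reassembly", mean=5, cv=0.9, size=50),
        ]
        winners = set()
        for _ in range(10):
            perm = list(base)
            rng.shuffle(perm)
            for c in perm:
                c.status = "validated"
            winners.add(rank_candidates(perm).donor_id)
        assert winners == {"d"}
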