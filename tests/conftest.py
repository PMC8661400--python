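import numpy as np
import pytest
from hypothesis import settings

from gapmend import Assembly, SeqEntry, run_curation, simulate_truth
from gapmend.synthetic_fixtures import DonorSpec, GapPlan, SyntheticConfig

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def small_config() -> SyntheticConfig:
    """A ~2 x 60 kb truth set: fast enough for unit tests, large enough to
    exercise anchoring, validation and telomere recovery."""
    plans = [
        GapPlan(0, "intergenic", 25, 400, slot=2),
        GapPlan(0, "within_gene", 200, 500, slot=5),
        GapPlan(1, "intergenic", 1000, 1000, slot=3),
    ]
    donors = [
        DonorSpec("re0", "reassembly", sub_rate=0.0),
        DonorSpec("alt1", "alternative", sub_rate=0.01),
    ]
    return SyntheticConfig(
        n_chromosomes=2,
        chromosome_length=60_000,
        genes_per_chromosome=8,
        gap_plans=plans,
        telomere_truncations=[(0, "right")],
        redundant_scaffolds=[2],
        novel_scaffolds=1,
        novel_scaffold_len=3000,
        donors=donors,
    )


@pytest.fixture(scope="session")
def small_truth():
    return simulate_truth(small_config(), seed=7)


@pytest.fixture(scope="session")
def small_result(small_truth):
    donors = {
        name: (asm, small_truth.donor_classes[name])
        for name, asm in small_truth.donors.items()
    }
    return run_curation(small_truth.reference, small_truth.genes, donors, small_truth.depth)


@pytest.fixture(scope="session")
def full_truth():
    return simulate_truth(seed=11)


def random_assembly(seed: int, lengths: dict[str, int]) -> Assembly:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return Assembly(
        [
            SeqEntry(sid, bases[rng.integers(0, 4, n)].tobytes().decode())
            for sid, n in lengths.items()
        ]
    )


def expected_corrected(truth_set) -> dict[str, str]:
    """Truth chromosomes with the *unclosable* planted gaps re-masked: the
    sequence a perfect curation run should produce from divergence-0 donors."""
    expected = {}
    for rec in truth_set.truth:
        seq = rec.sequence
        masks = [
            (p.truth_interval, p.gap_len)
            for p in truth_set.planted_gaps
            if p.seq_id == rec.seq_id and not p.closable
        ]
        for (lo, hi), gap_len in sorted(masks, reverse=True):
            seq = seq[:lo] + "N" * gap_len + seq[hi:]
        expected[rec.seq_id] = seq
    return expected
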