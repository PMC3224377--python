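import numpy as np
import pytest

from nucleoflex import (
    NucleosomeShape,
    SimConfig,
    StepStiffness,
    StiffnessTable,
    load_dinucleotide_table,
)
from nucleoflex import mnase, synth


@pytest.fixture(scope="session")
def dinuc_table() -> StiffnessTable:
    return load_dinucleotide_table()


@pytest.fixture(scope="session")
def ideal_shape() -> NucleosomeShape:
    return NucleosomeShape.ideal()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture()
def uniform_table() -> StiffnessTable:
    """All-contexts-identical table: zero equilibrium, diagonal stiffness
    with k_roll = 0.02 — for hand-checkable energies."""
    theta = np.diag([1.0, 1.0, 1.0, 1.0, 0.02, 1.0])
    entries = [
        StepStiffness(context=c, equilibrium=np.zeros(6), theta=theta)
        for c in ("AA", "AC", "AG", "AT", "CA", "CC", "CG", "GA", "GC", "TA")
    ]
    return StiffnessTable.from_entries(entries, level="dinucleotide")


@pytest.fixture(scope="session")
def chromatin_run():
    """One full synthetic chromatin experiment at default study conditions,
    shared by calling/classification/region tests."""
    cfg = SimConfig(seed=1, n_fragments=200_000)
    genome, truth = synth.generate_genome(cfg)
    truth = synth.place_nucleosomes(genome, truth, cfg)
    lengths = {c: len(s) for c, s in genome.items()}
    naked_reads, naked_pairs = synth.simulate_digestion(genome, cfg, None, stage=2)
    nuc_reads, nuc_pairs = synth.simulate_digestion(genome, cfg, truth.dyads, stage=3)

    def coverage(reads):
        frags = mnase.extend_reads(reads, 147, lengths)
        return mnase.rpm_normalize(mnase.build_coverage(frags, lengths))

    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "lengths": lengths,
        "naked_reads": naked_reads,
        "nuc_reads": nuc_reads,
        "naked_cov": coverage(naked_reads),
        "nuc_cov": coverage(nuc_reads),
    }
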