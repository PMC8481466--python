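import numpy as np
import pytest

from viropipe import curation, synthetic


@pytest.fixture(scope="session")
def small_community():
    """A small community with every genome role represented."""
    return synthetic.generate_genomes(20, 6, seed=11)


@pytest.fixture(scope="session")
def small_simulation(small_community):
    """Reads for a reduced two-arm design (fast enough for unit tests)."""
    design = synthetic.CommunityDesign(
        baseline_abundances={g: 150.0 for g in small_community.sequences},
        treatments=("Sham", "PFF+LPS"),
        n_animals_per_treatment=2,
        reads_per_sample=4_000,
        seed=11,
    )
    reads, truth, metadata = synthetic.simulate_reads(small_community, design)
    return design, reads, truth, metadata


@pytest.fixture(scope="session")
def curated_small(small_community):
    contigs = [
        curation.Contig(t.genome_id, small_community.sequences[t.genome_id])
        for t in small_community.truths
    ]
    evidence = curation.evidence_from_annotations(
        contigs, small_community.annotations, small_community.evidence_flags
    )
    return curation.curate(contigs, evidence)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
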