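"""Shared fixtures: published worked examples and a small synthetic dataset."""

from __future__ import annotations

import pytest

from mircurate import curation, synthetic
from mircurate.core_io import MiRNAGene

# The 13 novel cockroach miRNA genes with their published mature sequences
# (family-defining seed hexamers at positions 2-7).
TABLE2_MATURES: list[tuple[str, str]] = [
    ("Bge-Mir-bg1", "TGACTCCAGACCTTGTTGCTGA"),
    ("Bge-Mir-bg2", "TCGGACGAAGTGCACTTATTTACGT"),
    ("Bge-Mir-bg3a", "ATGAAATGGACGATTGGCTGTG"),
    ("Bge-Mir-bg3b", "TTGAAATGGACGATTGTCTGTG"),
    ("Bge-Mir-bg4a", "TACATAACCGCAATCACCGATT"),
    ("Bge-Mir-bg4b", "TACATAACCGCAACCACCGACT"),
    ("Bge-Mir-bg4c", "TACATAACCGCAACCACCGACT"),
    ("Bge-Mir-bg5a", "TGTGATGTGCATGTGGGCTTTCC"),
    ("Bge-Mir-bg5b", "TGTGATGTGCATGTGGGCTTTCC"),
    ("Bge-Mir-bg6", "TCACAACTTTCTGTCCAGAAC"),
    ("Bge-Mir-bg7", "CTACGAACCAGAATGACATCGCG"),
    ("Bge-Mir-bg8", "CATAGGCGCTATTTCCTCTGCC"),
    ("Bge-Mir-bg9", "CATTCTTCCTAGAATGGTCCGT"),
]

#: Rooted insect species topology used for the gain/loss analyses.
SPECIES_TREE_NEWICK = "((Bge,Lmi),(Api,(Ame,(Tca,(Bmo,Dme)))));"

#: Family presence patterns stated for the endopterygote transition, plus a
#: distractor family that arose one node deeper (coleopteran+panorpid stem).
ENDO_PRESENCE: dict[str, set[str]] = {
    "MIR-989": {"Ame", "Tca", "Bmo", "Dme"},
    "MIR-1006": {"Ame", "Bmo", "Dme"},
    "MIR-1007": {"Ame", "Dme"},
    "MIR-bg5": {"Bge", "Lmi", "Api"},
    "MIR-970": {"Tca", "Bmo", "Dme"},
}


@pytest.fixture(scope="session")
def table2_genes() -> list[MiRNAGene]:
    return [
        MiRNAGene(name, "", seq, "", "5p", "specific")
        for name, seq in TABLE2_MATURES
    ]


@pytest.fixture(scope="session")
def synthetic_dataset():
    """A small planted genome with simulated libraries (5 true + 5 decoys)."""
    genome, truth = synthetic.plant_mirna_loci(5, 5, 45_000, rng_seed=11)
    libs = synthetic.simulate_read_libraries(truth, 150, 2, 2, rng_seed=12)
    libraries = [lib for lib, _ in libs]
    reads = {lib.id: r for lib, r in libs}
    return {
        "genome": genome,
        "genome_dict": {genome.id: genome},
        "truth": truth,
        "libraries": libraries,
        "reads": reads,
    }


@pytest.fixture(scope="session")
def curated(synthetic_dataset):
    d = synthetic_dataset
    return curation.run_curation(
        d["genome_dict"],
        [p.candidate for p in d["truth"].planted_loci],
        d["libraries"],
        d["reads"],
    )
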