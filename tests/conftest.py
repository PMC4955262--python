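import numpy as np
import pytest

from pepthla.proteome import Peptide9, ProteinRecord, ProteinSet, ProteomeIndex
from pepthla.synthetic import FixtureSpec, PlantedOffTarget, PlantedTarget

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_index(rng: np.random.Generator, n: int) -> ProteomeIndex:
    """A proteome index of n distinct random 9-mers, one occurrence each."""
    peptides = {}
    letters = np.array(list(AA))
    while len(peptides) < n:
        block = letters[rng.integers(0, 20, size=(n, 9))]
        for row in block:
            seq = "".join(row)
            if seq not in peptides:
                peptides[seq] = Peptide9(seq, [(f"ACC{len(peptides)}",
                                                f"G{len(peptides)}", 1)])
            if len(peptides) == n:
                break
    return ProteomeIndex(peptides, n_proteins=n)


def mutate(rng: np.random.Generator, peptide: str, n_mut: int) -> str:
    pos = rng.choice(9, size=n_mut, replace=False)
    out = list(peptide)
    for p in pos:
        out[p] = AA[(AA.index(out[p]) + int(rng.integers(1, 20))) % 20]
    return "".join(out)


@pytest.fixture
def small_proteins() -> ProteinSet:
    return ProteinSet([
        ProteinRecord("P1", "GENEA", "KVAELVHFLACDEFGHIK"),
        ProteinRecord("P2", "GENEB", "MKVAELVHFL"),
        ProteinRecord("P3", "GENEC", "ACDEFGHIKXACDEFGHIK"),
    ])


@pytest.fixture
def planted_spec() -> FixtureSpec:
    """Two targets, three off-targets: the small end-to-end study."""
    return FixtureSpec(
        seed=7,
        planted_targets=[
            PlantedTarget("SLSVMSSNV", "SKCM", ic50_nM=265.87),
            PlantedTarget("LTSMWSPAV", "LAML", ic50_nM=279.13),
        ],
        planted_offtargets=[
            PlantedOffTarget("SLSVMSSNV", None, 6, "brain", ic50_nM=206.18),
            PlantedOffTarget("SLSVMSSNV", None, 5, "lung", ic50_nM=321.29),
            PlantedOffTarget("LTSMWSPAV", None, 7, "liver", ic50_nM=21.60),
        ],
    )
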