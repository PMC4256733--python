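import numpy as np
import pytest

from mitoevo.io_formats import GenomeMeta, PhyleticMatrix, SequenceRecord
from mitoevo.synthetic_data import SimulationConfig, simulate_tree
from mitoevo.trees import RootedTree


@pytest.fixture
def balanced8() -> RootedTree:
    return RootedTree.from_newick("(((S1,S2),(S3,S4)),((S5,S6),(S7,S8)));")


@pytest.fixture
def cherry() -> RootedTree:
    return RootedTree.from_newick("(A,B);")


def random_tree(n_leaves: int, seed: int) -> RootedTree:
    cfg = SimulationConfig(seed=seed, n_species=n_leaves)
    return simulate_tree(cfg)


def matrix_from_profiles(tree: RootedTree, profiles: list[dict[str, int]],
                         ) -> PhyleticMatrix:
    leaves = tree.leaf_names()
    cells = [[p[l] for l in leaves] for p in profiles]
    return PhyleticMatrix.from_arrays(
        [f"F{i + 1}" for i in range(len(profiles))], leaves, cells)


def toy_records():
    """Three tiny genomes with one obvious two-family structure."""
    records = [
        SequenceRecord("a1", "MKLVINGKTLKGEITVEGAKNAALPILAATLLA"),
        SequenceRecord("b1", "MKLVINGKTLKGEITVEGAKNAALPILAATLLA"),
        SequenceRecord("c1", "MKLVINGKTLRGEITVEGAKNAALPILAGTLLA"),
        SequenceRecord("a2", "MSHHWGYGKHNGPEHWHKDFPIAKGERQSPVDI"),
        SequenceRecord("b2", "MSHHWGYGKHNGPEHWHKDFPIAKGERQSPVDI"),
        SequenceRecord("c2", "MSHHWGYGKANGPEHWHKDFPIANGERQSPVDI"),
    ]
    meta = [GenomeMeta(r.seq_id, f"G{r.seq_id[0].upper()}", "mito",
                       ("Eukaryota", "CladeA")) for r in records]
    return records, meta
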