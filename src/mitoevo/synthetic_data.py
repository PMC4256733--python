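"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical regime the analyses assume:
protein families diverged along a species tree with presence/absence
shaped by lineage-specific loss from a gene-rich root; short fragments
and shuffled decoys to exercise the recruitment stage; and nuclear
orthologs whose introns evolve by single gain and multiple losses with
a configurable phase bias and a density deficit in a designated
"land-plant-like" focal clade.  Everything is bit-reproducible from
``(seed, config)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._alignment import AA_ORDER
from .io_formats import (
    GeneStructure,
    GenomeMeta,
    PhyleticMatrix,
    SequenceRecord,
    write_fasta,
    write_matrix_tsv,
    write_metadata,
    write_newick,
)
from .trees import RootedTree, TreeNode

# one unambiguous codon per residue, for writing synthetic CDS/GFF bundles
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_INTRON_SEQ = "GT" + "C" * 56 + "AG"  # fixed 60 nt synthetic intron


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults reproduce the regime the analyses are designed for:
    43-species trees, 71 gene families all observed at the root, a
    5:3:2 intron phase bias and a 1.5-fold intron-density deficit in
    the focal clade.  Clustering simulations use smaller per-call
    arguments (10 genomes, 30 families) set by their own defaults.
    """

    seed: int = 0
    n_species: int = 43
    n_families: int = 71
    root_lambda: float | None = None  # Poisson root count; None = exactly n_families
    loss_prob: float = 0.15           # per-branch gene-loss probability
    min_present: int = 1              # rejection: families observed in >= this many leaves
    branch_length_mean: float = 0.25
    # protein families
    seq_length: tuple[int, int] = (90, 150)
    substitution_prob: float = 0.05   # per site per branch
    min_present_per_family: int = 3   # clustering needs 3-genome triangles
    n_fragments: int = 5
    fragment_fraction: float = 0.6
    n_decoys: int = 5
    # intron histories
    n_codons: int = 300
    intron_density: float = 4.0       # introns per kb coding sequence (background)
    intron_loss_prob: float = 0.1     # per branch below the gain
    phase_bias: tuple[float, float, float] = (0.5, 0.3, 0.2)
    focal_deficit: float = 1.0 / 1.5  # focal-clade density multiplier
    focal_fraction: float = 0.25      # focal clade targets this share of species

    def __post_init__(self):
        for p in (self.loss_prob, self.substitution_prob, self.intron_loss_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be within [0, 1]")
        if self.substitution_prob >= 0.5:
            raise ValueError("substitution probability must be < 0.5")
        if abs(sum(self.phase_bias) - 1.0) > 1e-9:
            raise ValueError("phase bias must sum to 1")
        if self.focal_deficit <= 0:
            raise ValueError("focal deficit factor must be positive")
        if self.intron_density <= 0:
            raise ValueError("intron density target must be positive")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(config: SimulationConfig) -> RootedTree:
    """Random bifurcating rooted tree by sequential random leaf attachment."""
    if config.n_species < 2:
        raise ValueError("need at least two species")
    rng = _rng(config, 1)
    width = len(str(config.n_species))
    names = [f"S{i + 1:0{width}d}" for i in range(config.n_species)]
    root = TreeNode()
    root.add_child(TreeNode(name=names[0]))
    root.add_child(TreeNode(name=names[1]))
    attachable = list(root.children)  # nodes with a branch above them
    for name in names[2:]:
        target = attachable[rng.integers(len(attachable))]
        parent = target.parent
        middle = TreeNode()
        parent.children[parent.children.index(target)] = middle
        middle.parent = parent
        middle.add_child(target)
        leaf = TreeNode(name=name)
        middle.add_child(leaf)
        attachable.extend([middle, leaf])
    tree = RootedTree(root)
    for node in tree.preorder():
        if node.parent is not None:
            node.length = float(rng.exponential(config.branch_length_mean))
    return RootedTree.from_newick(tree.to_newick())  # re-assign stable ids


# ---------------------------------------------------------------------------
# gene content
# ---------------------------------------------------------------------------

def simulate_gene_content(tree: RootedTree, config: SimulationConfig,
                          min_present: int | None = None,
                          retry_cap: int = 1000,
                          ) -> tuple[PhyleticMatrix, dict]:
    """Presence/absence profiles under lineage-specific loss.

    The family count at the root is Poisson(``root_lambda``) when that
    is set, otherwise exactly ``n_families``.  Each family survives the
    branch above node *c* with probability ``1 - loss_prob``; profiles
    with fewer than ``min_present`` present leaves are rejected and
    redrawn (up to ``retry_cap`` attempts per family).
    """
    rng = _rng(config, 2)
    min_present = config.min_present if min_present is None else min_present
    if config.root_lambda is not None:
        n_families = int(rng.poisson(config.root_lambda))
    else:
        n_families = config.n_families
    q = {n.id: config.loss_prob for n in tree.preorder() if n.parent is not None}
    leaf_names = tree.leaf_names()
    width = len(str(max(n_families, 1)))
    family_ids = [f"F{i + 1:0{width}d}" for i in range(n_families)]
    cells = np.zeros((n_families, len(leaf_names)), dtype=np.int8)
    loss_events: dict[str, list[str]] = {}
    for i, fam in enumerate(family_ids):
        for attempt in range(retry_cap):
            presence, losses = _drop_family(tree, q, rng)
            if sum(presence.values()) >= min_present:
                break
        else:
            raise RuntimeError(
                f"rejection cap reached for family {fam!r}: loss probability "
                "too high for the requested minimum presence")
        cells[i] = [presence[name] for name in leaf_names]
        loss_events[fam] = losses
    matrix = PhyleticMatrix.from_arrays(family_ids, leaf_names, cells)
    truth = {"q": q, "loss_events": loss_events, "root_count": n_families}
    return matrix, truth


def _drop_family(tree, q, rng):
    state = {tree.root.id: 1}
    losses = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        if state[node.parent.id] == 0:
            state[node.id] = 0
        elif rng.random() < q[node.id]:
            state[node.id] = 0
            losses.append(node.id)
        else:
            state[node.id] = 1
    presence = {leaf.name: state[leaf.id] for leaf in tree.leaves()}
    return presence, losses


# ---------------------------------------------------------------------------
# protein families
# ---------------------------------------------------------------------------

def simulate_protein_families(tree: RootedTree, config: SimulationConfig,
                              ) -> tuple[list[SequenceRecord], list[GenomeMeta], dict]:
    """Protein families diverged along the tree, with fragments and decoys.

    Per family a random root protein evolves down the tree (each site
    substitutes to a random different residue with
    ``substitution_prob`` per branch); presence follows the gene-loss
    process conditioned on at least ``min_present_per_family`` genomes.
    Truncated fragments (recruitment targets) and residue-shuffled
    decoys (negative controls) are appended with labels in the truth.
    """
    rng = _rng(config, 3)
    content, _ = simulate_gene_content(
        tree, config, min_present=config.min_present_per_family)
    aa = np.array(list(AA_ORDER))
    leaf_names = tree.leaf_names()
    group_of = _clade_labels(tree)
    records: list[SequenceRecord] = []
    meta: list[GenomeMeta] = []
    family_of: dict[str, str] = {}
    lo, hi = config.seq_length
    for i, fam in enumerate(content.family_ids):
        length = int(rng.integers(lo, hi + 1))
        root_seq = aa[rng.integers(0, 20, length)]
        seqs = {tree.root.id: root_seq}
        for node in tree.preorder():
            if node.parent is None:
                continue
            parent_seq = seqs[node.parent.id]
            child = parent_seq.copy()
            mutate = rng.random(length) < config.substitution_prob
            for pos in np.where(mutate)[0]:
                choices = [a for a in AA_ORDER if a != child[pos]]
                child[pos] = choices[rng.integers(19)]
            seqs[node.id] = child
        row = content.frame.loc[fam]
        for leaf in tree.leaves():
            if not row[leaf.name]:
                continue
            seq_id = f"{fam}_{leaf.name}"
            records.append(SequenceRecord(seq_id, "".join(seqs[leaf.id])))
            meta.append(GenomeMeta(seq_id, leaf.name, "mito",
                                   ("Eukaryota", group_of[leaf.name])))
            family_of[seq_id] = fam
    # fragments: prefix truncations of existing members (same genome)
    members = sorted(family_of)
    fragments: dict[str, str] = {}
    for _ in range(config.n_fragments):
        parent_id = members[rng.integers(len(members))]
        parent = next(r for r in records if r.seq_id == parent_id)
        frag_len = max(10, int(round(config.fragment_fraction * parent.length)))
        frag_id = f"{parent_id}_frag"
        if any(r.seq_id == frag_id for r in records):
            continue
        records.append(SequenceRecord(frag_id, parent.residues[:frag_len]))
        genome = next(m.genome_id for m in meta if m.seq_id == parent_id)
        meta.append(GenomeMeta(frag_id, genome, "mito",
                               ("Eukaryota", group_of[genome])))
        fragments[frag_id] = family_of[parent_id]
    # decoys: residue-shuffled copies of random members, emitted in the
    # source member's own genome.  Keeping the real member alongside its
    # shuffle means a decoy can never be "best hit by default" in a
    # genome that lacks the family, so decoys probe exactly the
    # recruitment-stage null (composition without positional signal).
    decoys: list[str] = []
    for k in range(config.n_decoys):
        parent_id = members[rng.integers(len(members))]
        parent = next(r for r in records if r.seq_id == parent_id)
        shuffled = "".join(rng.permutation(list(parent.residues)))
        decoy_id = f"decoy{k + 1:02d}"
        genome = next(m.genome_id for m in meta if m.seq_id == parent_id)
        records.append(SequenceRecord(decoy_id, shuffled))
        meta.append(GenomeMeta(decoy_id, genome, "mito",
                               ("Eukaryota", group_of[genome])))
        decoys.append(decoy_id)
    truth = {"family_of": family_of, "fragments": fragments, "decoys": decoys,
             "content": {f: content.profile(f) for f in content.family_ids}}
    return records, meta, truth


def _clade_labels(tree: RootedTree) -> dict[str, str]:
    labels = {}
    for k, child in enumerate(tree.root.children):
        tag = f"Clade{chr(ord('A') + k)}"
        stack = [child]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                labels[node.name] = tag
            stack.extend(node.children)
    return labels


# ---------------------------------------------------------------------------
# intron histories
# ---------------------------------------------------------------------------

def pick_focal_clade(tree: RootedTree, fraction: float = 0.25) -> TreeNode:
    """Internal node whose leaf count is closest to ``fraction`` of species."""
    target = fraction * len(tree.leaves())
    best = None
    best_gap = None
    for node in tree.preorder():
        if node.is_leaf or node.parent is None:
            continue
        size = sum(1 for _ in _leaves_under(node))
        gap = abs(size - target)
        if best_gap is None or gap < best_gap:
            best, best_gap = node, gap
    return best if best is not None else tree.root


def _leaves_under(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        stack.extend(n.children)


def simulate_intron_histories(tree: RootedTree, config: SimulationConfig,
                              ) -> tuple[list[GeneStructure], dict[str, str], dict]:
    """Orthologous nuclear genes with single-gain / multi-loss introns.

    One equal-length gene per species (so the true protein alignment is
    the identity).  Each intron character is gained once on a random
    node, survives each branch below with ``1 - intron_loss_prob``, and
    carries a phase drawn from the configured bias.  Species in the
    focal clade additionally retain each intron with probability
    ``focal_deficit``, producing the planted density deficit.
    """
    rng = _rng(config, 4)
    leaf_names = tree.leaf_names()
    n_sp = len(leaf_names)
    cds_len = 3 * config.n_codons
    # expected leaves present per character, for calibrating the character count
    nodes = [n for n in tree.preorder()]
    survival = {tree.root.id: 1.0}
    for node in tree.preorder():
        if node.parent is not None:
            survival[node.id] = survival[node.parent.id] * (1 - config.intron_loss_prob)
    mean_presence = 0.0
    for gain in nodes:
        base = survival[gain.id]
        mean_presence += sum(survival[l.id] / base for l in _leaves_under(gain))
    mean_presence /= len(nodes)
    target_total = config.intron_density * (cds_len / 1000.0) * n_sp
    n_chars = max(1, int(round(target_total / mean_presence)))

    focal = pick_focal_clade(tree, config.focal_fraction)
    focal_species = {l.name for l in _leaves_under(focal)}

    used_offsets: set[int] = set()
    characters = []
    for k in range(n_chars):
        for _ in range(1000):
            codon = int(rng.integers(1, config.n_codons))
            phase = int(rng.choice(3, p=np.asarray(config.phase_bias)))
            offset = 3 * codon + phase
            if offset not in used_offsets:
                used_offsets.add(offset)
                break
        else:
            break  # coding sequence saturated with intron positions
        gain = nodes[rng.integers(len(nodes))]
        state = {gain.id: 1}
        losses = []
        stack = list(gain.children)
        while stack:
            node = stack.pop()
            if state[node.parent.id] == 0:
                state[node.id] = 0
            elif rng.random() < config.intron_loss_prob:
                state[node.id] = 0
                losses.append(node.id)
            else:
                state[node.id] = 1
            stack.extend(node.children)
        present = {l.name for l in _leaves_under(gain) if state.get(l.id, 0) == 1}
        thinned = []
        for sp in sorted(present & focal_species):
            if rng.random() > config.focal_deficit:
                present.discard(sp)
                thinned.append(sp)
        characters.append({
            "id": f"ic{k + 1:03d}", "offset": int(offset),
            "gain": gain.id, "losses": sorted(losses),
            "present": sorted(present), "focal_thinned": thinned,
        })

    # one orthologous protein per species, evolved for sequence realism
    aa = np.array(list(AA_ORDER))
    root_seq = aa[rng.integers(0, 20, config.n_codons)]
    seqs = {tree.root.id: root_seq}
    for node in tree.preorder():
        if node.parent is None:
            continue
        child = seqs[node.parent.id].copy()
        mutate = rng.random(config.n_codons) < config.substitution_prob
        for pos in np.where(mutate)[0]:
            choices = [a for a in AA_ORDER if a != child[pos]]
            child[pos] = choices[rng.integers(19)]
        seqs[node.id] = child

    structures = []
    alignment = {}
    for leaf in tree.leaves():
        gene_id = f"g_{leaf.name}"
        offsets = tuple(sorted(
            ch["offset"] for ch in characters if leaf.name in ch["present"]))
        structures.append(GeneStructure(gene_id, leaf.name, cds_len, offsets))
        alignment[gene_id] = "".join(seqs[leaf.id])
    truth = {
        "characters": characters,
        "focal_clade": focal.id,
        "focal_species": sorted(focal_species),
        "n_characters": len(characters),
    }
    return structures, alignment, truth


# ---------------------------------------------------------------------------
# complete bundle on disk
# ---------------------------------------------------------------------------

def make_toy_dataset(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write a complete, internally consistent input bundle.

    Produces FASTA + metadata, a species tree, a gene-content matrix,
    an intron gene set (GFF3 + CDS FASTA + protein alignment) and a
    truth JSON.  Returns a name -> path map; deterministic per seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(config)
    content, content_truth = simulate_gene_content(tree, config)
    records, meta, family_truth = simulate_protein_families(tree, config)
    structures, alignment, intron_truth = simulate_intron_histories(tree, config)

    paths = {name: str(out / name) for name in (
        "species_tree.nwk", "proteins.fasta", "metadata.tsv",
        "gene_content.tsv", "genes.gff3", "cds.fasta",
        "protein_alignment.fasta", "truth.json")}
    write_newick(tree, paths["species_tree.nwk"])
    write_fasta(records, paths["proteins.fasta"])
    write_metadata(meta, paths["metadata.tsv"])
    write_matrix_tsv(content, paths["gene_content.tsv"])
    _write_gene_bundle(structures, alignment, paths["genes.gff3"], paths["cds.fasta"])
    with open(paths["protein_alignment.fasta"], "w") as fh:
        for gene_id in sorted(alignment):
            fh.write(f">{gene_id}\n{alignment[gene_id]}\n")
    truth = {
        "config": {k: v for k, v in asdict(config).items()},
        "gene_content": content_truth,
        "families": family_truth,
        "introns": intron_truth,
        "n_families": len(content.family_ids),
    }
    with open(paths["truth.json"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=list)
    return paths


def _write_gene_bundle(structures, alignment, gff_path, cds_path) -> None:
    with open(gff_path, "w") as gff, open(cds_path, "w") as cds:
        gff.write("##gff-version 3\n")
        for s in sorted(structures, key=lambda x: x.gene_id):
            protein = alignment[s.gene_id].replace("-", "")
            cds_seq = "".join(_CODON[c] for c in protein)
            cds.write(f">{s.gene_id}\n{cds_seq}\n")
            boundaries = [0, *s.introns, s.cds_length]
            genomic = 1
            for exon_start, exon_end in zip(boundaries, boundaries[1:]):
                length = exon_end - exon_start
                gff.write("\t".join([
                    f"chr_{s.species_id}", "mitoevo", "CDS",
                    str(genomic), str(genomic + length - 1), ".", "+", ".",
                    f"Parent={s.gene_id};species={s.species_id}",
                ]) + "\n")
                genomic += length + len(_INTRON_SEQ)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
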