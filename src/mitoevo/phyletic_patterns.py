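"""Phyletic pattern analyses.

Presence/absence and compartment matrices over (family, species),
per-genome clustering coverage summaries, the Fisher exact test for
enrichment of dual (mitochondrial + nuclear) encoding in a focal set of
species, and gene-tree vetting of candidate nuclear orthologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cog_builder import ClusterSet
from .io_formats import GenomeMeta, PhyleticMatrix
from .trees import RootedTree

COMPARTMENT_CODES = {"absent": ".", "mito": "M", "nuclear": "N",
                     "dual": "D", "other": "O"}
_CODE_TO_STATE = {v: k for k, v in COMPARTMENT_CODES.items()}

LEAF_CLASSES = frozenset({"mito", "alpha", "cyano", "archaea",
                          "nuclear-candidate", "other"})


class CompartmentMatrix:
    """Families x species matrix of encoding states.

    States: ``absent``, ``mito``, ``nuclear``, ``dual`` (both genomes of
    the same species carry the gene) and ``other`` (present only via a
    non-mito, non-nuclear compartment such as a bacterial outgroup).
    """

    STATES = frozenset(COMPARTMENT_CODES)

    def __init__(self, frame: pd.DataFrame):
        bad = set(np.unique(frame.to_numpy())) - self.STATES if frame.size else set()
        if bad:
            raise ValueError(f"unknown compartment states {sorted(bad)}")
        self.frame = frame

    @property
    def family_ids(self):
        return list(self.frame.index)

    @property
    def species_ids(self):
        return list(self.frame.columns)

    def to_presence(self) -> PhyleticMatrix:
        return PhyleticMatrix((self.frame != "absent").astype(np.int8))

    def write_tsv(self, path) -> None:
        self.frame.replace(COMPARTMENT_CODES).to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "CompartmentMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        return cls(frame.replace(_CODE_TO_STATE))


def build_matrices(clusters: ClusterSet, meta: list[GenomeMeta],
                   species_order: list[str],
                   ) -> tuple[PhyleticMatrix, CompartmentMatrix]:
    """Presence and compartment matrices from a cluster partition.

    Presence is 1 iff the family has at least one member in the species
    (any compartment); the compartment cell is ``dual`` iff the species
    has both a mito- and a nuclear-compartment member.
    """
    by_seq = {m.seq_id: m for m in meta}
    known = set(species_order)
    for cluster in clusters.clusters.values():
        for seq_id in cluster.members:
            g = by_seq[seq_id].genome_id
            if g not in known:
                raise ValueError(
                    f"genome {g!r} (sequence {seq_id!r}) missing from species_order")
    family_ids = sorted(clusters.clusters)
    presence = np.zeros((len(family_ids), len(species_order)), dtype=np.int8)
    states = np.full((len(family_ids), len(species_order)), "absent", dtype=object)
    col = {s: j for j, s in enumerate(species_order)}
    for i, cid in enumerate(family_ids):
        compartments: dict[str, set[str]] = {}
        for seq_id in clusters.clusters[cid].members:
            m = by_seq[seq_id]
            compartments.setdefault(m.genome_id, set()).add(m.compartment)
        for genome_id, comps in compartments.items():
            j = col[genome_id]
            presence[i, j] = 1
            if "mito" in comps and "nuclear" in comps:
                states[i, j] = "dual"
            elif "mito" in comps:
                states[i, j] = "mito"
            elif "nuclear" in comps:
                states[i, j] = "nuclear"
            else:
                states[i, j] = "other"
    pm = PhyleticMatrix.from_arrays(family_ids, species_order, presence)
    cm = CompartmentMatrix(pd.DataFrame(states, index=family_ids,
                                        columns=list(species_order)))
    return pm, cm


@dataclass
class CoverageReport:
    """Per-genome clustering coverage with per-taxon summaries."""

    per_genome: dict[str, float | None]
    per_group: dict[str, dict[str, float]]  # group -> {min, median, max, n}

    def to_json_dict(self) -> dict:
        return {"per_genome": self.per_genome, "per_group": self.per_group}


def coverage_report(clusters: ClusterSet, meta: list[GenomeMeta],
                    exclude_origins: set[str] = frozenset({"orphan"}),
                    group_depth: int = 1) -> CoverageReport:
    """Fraction of each genome's mito proteins assigned to real clusters.

    Clusters whose origin is in ``exclude_origins`` do not count as
    assignments.  Genomes with zero mito-compartment proteins report
    ``None`` and are excluded from group summaries.  Grouping uses the
    lineage label at ``group_depth`` (default: the second level).
    """
    excluded_clusters = {cid for cid, c in clusters.clusters.items()
                         if c.origin in exclude_origins}
    assigned: set[str] = set()
    for cid, cluster in clusters.clusters.items():
        if cid not in excluded_clusters:
            assigned |= cluster.members
    totals: dict[str, int] = {}
    counted: dict[str, int] = {}
    group_of: dict[str, str] = {}
    for m in meta:
        group_of.setdefault(
            m.genome_id,
            m.taxon_path[min(group_depth, len(m.taxon_path) - 1)])
        if m.compartment != "mito":
            continue
        totals[m.genome_id] = totals.get(m.genome_id, 0) + 1
        if m.seq_id in assigned:
            counted[m.genome_id] = counted.get(m.genome_id, 0) + 1
    per_genome: dict[str, float | None] = {}
    for genome_id in sorted(group_of):
        n = totals.get(genome_id, 0)
        per_genome[genome_id] = (counted.get(genome_id, 0) / n) if n else None
    groups: dict[str, list[float]] = {}
    for genome_id, frac in per_genome.items():
        if frac is None:
            continue
        groups.setdefault(group_of[genome_id], []).append(frac)
    per_group = {}
    for group, fractions in sorted(groups.items()):
        per_group[group] = {
            "min": float(min(fractions)),
            "median": float(np.median(fractions)),
            "max": float(max(fractions)),
            "n": len(fractions),
        }
    return CoverageReport(per_genome, per_group)


# ---------------------------------------------------------------------------
# Fisher exact test for dual-encoding enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float  # nan when undefined
    p_value: float
    convention: str
    odds_ratio_defined: bool


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     convention: str = "minlike") -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    ``minlike``: sum of the probabilities of all tables (same margins)
    whose point probability is at most the observed one.  ``doubled``:
    twice the smaller one-sided tail, capped at 1.  Both are in common
    use; published values often do not state which was applied.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    if convention == "minlike":
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    if convention == "doubled":
        n = a + b + c + d
        dist = stats.hypergeom(n, a + b, a + c)
        lower = dist.cdf(a)
        upper = dist.sf(a - 1)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown convention {convention!r}")


def dual_encoding_enrichment(compartments: CompartmentMatrix,
                             focal_species: list[str],
                             background_species: list[str],
                             convention: str = "minlike",
                             ) -> EnrichmentResult:
    """Fisher test for enrichment of dual encoding in a focal species set.

    The 2x2 table contrasts counts of dual (family, species) gene
    instances with the species counts themselves: a = dual instances in
    the focal set, b = dual instances in the background set, c = number
    of focal species, d = number of background species.  Odds ratio is
    ad/bc.
    """
    focal = list(focal_species)
    background = list(background_species)
    if not focal or not background:
        raise ValueError("focal and background sets must be non-empty")
    if set(focal) & set(background):
        raise ValueError("focal and background sets must be disjoint")
    frame = compartments.frame
    a = int((frame[focal] == "dual").to_numpy().sum())
    b = int((frame[background] == "dual").to_numpy().sum())
    c, d = len(focal), len(background)
    p = fisher_exact_2x2(a, b, c, d, convention)
    defined = b * c > 0
    odds = (a * d) / (b * c) if defined else math.nan
    return EnrichmentResult((a, b, c, d), odds, p, convention, defined)


# ---------------------------------------------------------------------------
# gene-tree vetting of nuclear ortholog candidates
# ---------------------------------------------------------------------------

def vet_nuclear_orthologs(gene_tree: RootedTree,
                          leaf_classes: dict[str, str]) -> list[str]:
    """Accept nuclear candidates that form a clade with mito (+alpha) leaves.

    A ``nuclear-candidate`` leaf is accepted iff the smallest clade
    containing it and at least one ``mito`` leaf contains only leaves of
    classes {mito, alpha, nuclear-candidate}.  This replaces the manual
    tree inspection of the original protocol with a reproducible rule.
    """
    allowed = {"mito", "alpha", "nuclear-candidate"}
    leaves = gene_tree.leaves()
    for leaf in leaves:
        cls = leaf_classes.get(leaf.name)
        if cls is None:
            raise ValueError(f"leaf {leaf.name!r} has no class")
        if cls not in LEAF_CLASSES:
            raise ValueError(f"leaf {leaf.name!r}: unknown class {cls!r}")
    # classes of the leaf set below each node
    below: dict[int, set[str]] = {}
    has_mito: dict[int, bool] = {}
    classes_below: dict[int, set[str]] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            classes_below[id(node)] = {leaf_classes[node.name]}
        else:
            classes_below[id(node)] = set().union(
                *(classes_below[id(c)] for c in node.children))
    accepted = []
    for leaf in leaves:
        if leaf_classes[leaf.name] != "nuclear-candidate":
            continue
        node = leaf
        while node is not None and "mito" not in classes_below[id(node)]:
            node = node.parent
        if node is None:
            continue  # no mito leaf anywhere: reject
        if classes_below[id(node)] <= allowed:
            accepted.append(leaf.name)
    return sorted(accepted)


def read_leaf_classes(path) -> dict[str, str]:
    """Read a leaf-class TSV (leaf <tab> class)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["leaf", "class"]:
        frame.columns = ["leaf", "class"] + list(frame.columns[2:])
    return dict(zip(frame["leaf"], frame["class"]))
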