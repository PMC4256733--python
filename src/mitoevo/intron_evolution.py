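"""Exon-intron architecture analytics.

Intron positions live in coding-sequence space: an intron's offset is
the number of coding nucleotides 5' of it, so phase is ``offset % 3``
and untranslated regions are irrelevant.  A protein multiple alignment
is expanded codon-wise (one protein column -> three nucleotide
columns) to project intron positions onto common coordinates; two
introns are shared iff they map to exactly the same alignment
nucleotide column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneStructure, PhyleticMatrix


def intron_density(structures: list[GeneStructure]) -> float:
    """Introns per 1 kb of coding sequence, pooled over the input genes."""
    if not structures:
        raise ValueError("no gene structures")
    total_nt = sum(s.cds_length for s in structures)
    if total_nt == 0:
        raise ValueError("zero total coding length")
    total_introns = sum(len(s.introns) for s in structures)
    return 1000.0 * total_introns / total_nt


@dataclass(frozen=True)
class PhaseSpectrum:
    counts: tuple[int, int, int]
    fractions: tuple[float, float, float] | None  # None when no introns

    @property
    def n(self) -> int:
        return sum(self.counts)


def phase_spectrum(structures: list[GeneStructure]) -> PhaseSpectrum:
    """Counts and fractions of phase 0/1/2 introns."""
    counts = [0, 0, 0]
    for s in structures:
        for phase in s.phases():
            counts[phase] += 1
    total = sum(counts)
    fractions = tuple(c / total for c in counts) if total else None
    return PhaseSpectrum(tuple(counts), fractions)


@dataclass(frozen=True)
class ExonSymmetrySpectrum:
    """Counts of internal exons by (upstream phase, downstream phase)."""

    classes: dict[tuple[int, int], int]
    n_terminal: int  # first/last exons, excluded from the 9 classes

    def symmetric_count(self) -> int:
        return sum(v for (a, b), v in self.classes.items() if a == b)


def exon_symmetry_spectrum(structures: list[GeneStructure]) -> ExonSymmetrySpectrum:
    """Classify internal exons by the phases of their flanking introns."""
    classes = {(a, b): 0 for a in range(3) for b in range(3)}
    n_terminal = 0
    for s in structures:
        phases = s.phases()
        if not phases:
            continue  # single-exon gene: no intron-flanked exon at all
        n_terminal += 2  # first and last exon of an intron-bearing gene
        for up, down in zip(phases, phases[1:]):
            classes[(up, down)] += 1
    return ExonSymmetrySpectrum(classes, n_terminal)


# ---------------------------------------------------------------------------
# codon-aware projection
# ---------------------------------------------------------------------------

class CodonAlignment:
    """Protein alignment with a back-translated nucleotide coordinate map.

    For each gene, ``maps[gene_id][k]`` is the alignment nucleotide
    column of ungapped coding offset ``k`` (0 <= k < cds_length); the
    mapping is strictly increasing and column = 3 * protein column +
    codon position.
    """

    def __init__(self, rows: dict[str, str], maps: dict[str, np.ndarray]):
        self.rows = rows
        self.maps = maps
        widths = {len(r) for r in rows.values()}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")
        self.n_columns = 3 * widths.pop() if widths else 0

    def column_of(self, gene_id: str, offset: int) -> int:
        mapping = self.maps[gene_id]
        if not (0 <= offset < mapping.shape[0]):
            raise ValueError(
                f"gene {gene_id!r}: coding offset {offset} outside mapped "
                f"range [0, {mapping.shape[0]})")
        return int(mapping[offset])


def backtranslate_alignment(protein_alignment: dict[str, str],
                            structures: list[GeneStructure]) -> CodonAlignment:
    """Expand a protein alignment to nucleotide coordinates.

    Each gene's ungapped row length times 3 must equal its
    ``cds_length`` (stop codon excluded).  A protein gap becomes three
    nucleotide gaps, so the mapping of coding offset to alignment
    column is ``3 * aligned_protein_column + offset % 3``.
    """
    by_gene = {s.gene_id: s for s in structures}
    maps: dict[str, np.ndarray] = {}
    for gene_id, row in protein_alignment.items():
        if gene_id not in by_gene:
            raise ValueError(f"alignment row {gene_id!r} has no gene structure")
        n_res = len(row) - row.count("-")
        expected = 3 * n_res
        cds_len = by_gene[gene_id].cds_length
        if expected != cds_len:
            raise ValueError(
                f"gene {gene_id!r}: alignment row has {n_res} residues "
                f"({expected} nt) but cds_length is {cds_len}")
        mapping = np.empty(cds_len, dtype=np.int64)
        k = 0
        for column, char in enumerate(row):
            if char == "-":
                continue
            base = 3 * column
            mapping[k:k + 3] = (base, base + 1, base + 2)
            k += 3
        maps[gene_id] = mapping
    return CodonAlignment(dict(protein_alignment), maps)


class SharedIntronMatrix:
    """Species x species shared-intron-position counts.

    Off-diagonal cells count alignment columns where both species carry
    an intron; diagonal cells count columns private to that species.
    """

    def __init__(self, frame: pd.DataFrame):
        if not frame.index.equals(frame.columns):
            raise ValueError("matrix must be square with matching labels")
        values = frame.to_numpy()
        if (values < 0).any() or not np.array_equal(values, values.T):
            raise ValueError("shared-intron matrix must be symmetric, non-negative")
        self.frame = frame

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


def project_and_share(alignment: CodonAlignment,
                      structures: list[GeneStructure],
                      ) -> tuple[dict[str, list[int]], SharedIntronMatrix]:
    """Map introns to alignment columns and count shared positions.

    Returns per-gene projected columns and the species-level shared
    matrix.  Equal columns imply equal phase (the codon-wise expansion
    preserves frame); this is asserted as a sanity check.
    """
    positions: dict[str, list[int]] = {}
    species_columns: dict[str, set[int]] = {}
    for s in structures:
        if s.gene_id not in alignment.maps:
            raise ValueError(f"gene {s.gene_id!r} missing from the alignment")
        cols = [alignment.column_of(s.gene_id, off) for off in s.introns]
        for off, c in zip(s.introns, cols):
            assert c % 3 == off % 3, "column/phase mismatch in projection"
        positions[s.gene_id] = cols
        species_columns.setdefault(s.species_id, set()).update(cols)
    species = sorted(species_columns)
    n = len(species)
    counts = np.zeros((n, n), dtype=int)
    for i, a in enumerate(species):
        for j, b in enumerate(species):
            if i < j:
                shared = len(species_columns[a] & species_columns[b])
                counts[i, j] = counts[j, i] = shared
    for i, a in enumerate(species):
        private = set(species_columns[a])
        for j, b in enumerate(species):
            if i != j:
                private -= species_columns[b]
        counts[i, i] = len(private)
    frame = pd.DataFrame(counts, index=species, columns=species)
    return positions, SharedIntronMatrix(frame)


def intron_presence_matrix(alignment: CodonAlignment,
                           structures: list[GeneStructure]) -> PhyleticMatrix:
    """One binary character per intron-bearing alignment column.

    Characters are named ``pos<column>`` and ordered by column; the
    cell is 1 iff the species has an intron at that column.  The result
    feeds Dollo reconstruction directly.
    """
    positions, _ = project_and_share(alignment, structures)
    species_of = {s.gene_id: s.species_id for s in structures}
    species = sorted({s.species_id for s in structures})
    by_column: dict[int, set[str]] = {}
    for gene_id, cols in positions.items():
        for c in cols:
            by_column.setdefault(c, set()).add(species_of[gene_id])
    columns = sorted(by_column)
    cells = np.zeros((len(columns), len(species)), dtype=np.int8)
    for i, c in enumerate(columns):
        for j, sp in enumerate(species):
            cells[i, j] = 1 if sp in by_column[c] else 0
    return PhyleticMatrix.from_arrays([f"pos{c}" for c in columns], species, cells)


# ---------------------------------------------------------------------------
# density comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p_value: float
    expected: tuple[float, float, float, float]
    low_expected_warning: bool


def density_chi2_test(focal_structures: list[GeneStructure],
                      reference_intron_count: int,
                      reference_position_count: int) -> Chi2Result:
    """Chi-squared comparison of intron frequency against a reference.

    The 2x2 table contrasts intron-bearing vs non-intron coding
    positions in the focal gene set against reference counts (taken
    from genome-scale estimates, supplied as two integers).  No
    continuity correction; df = 1.  Expected cells below 1 set a
    warning flag rather than raising.
    """
    if reference_position_count <= 0:
        raise ValueError("reference position count must be positive")
    if reference_intron_count < 0 or reference_intron_count > reference_position_count:
        raise ValueError("reference intron count outside [0, positions]")
    k1 = sum(len(s.introns) for s in focal_structures)
    n1 = sum(s.cds_length for s in focal_structures)
    if n1 <= 0:
        raise ValueError("focal set has zero coding positions")
    k2, n2 = reference_intron_count, reference_position_count
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    pooled = (k1 + k2) / (n1 + n2)
    expected = np.array([[n1 * pooled, n1 * (1 - pooled)],
                         [n2 * pooled, n2 * (1 - pooled)]])
    if pooled in (0.0, 1.0):
        chi2 = 0.0
    else:
        chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return Chi2Result(chi2, 1, p, tuple(expected.ravel()),
                      bool((expected < 1).any()))
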