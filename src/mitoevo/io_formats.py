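"""Readers and writers for the standard formats the pipeline touches.

All coordinate conversion happens here: GFF3 comes in 1-based inclusive
and leaves as 0-based offsets into the spliced coding sequence; BLAST
tabular rows come in the 14-column ``6 std qlen slen`` dialect so that
query/subject coverage can be computed without a separate length table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .trees import RootedTree, TreeNode  # noqa: F401  (re-exported)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = set("ACGTN")
COMPARTMENTS = frozenset({"mito", "nuclear", "alpha", "cyano", "archaea", "other"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A protein (or nucleotide) sequence with a unique identifier."""

    seq_id: str
    residues: str

    def __post_init__(self):
        if not self.seq_id:
            raise ValueError("empty seq_id")
        if not self.residues:
            raise ValueError(f"record {self.seq_id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomeMeta:
    """Provenance of one sequence: genome, compartment and lineage."""

    seq_id: str
    genome_id: str
    compartment: str
    taxon_path: tuple[str, ...]

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r} for {self.seq_id!r}; "
                f"expected one of {sorted(COMPARTMENTS)}"
            )


@dataclass(frozen=True)
class SimilarityHit:
    """A scored local-alignment hit between two sequences."""

    query: str
    subject: str
    score: float
    evalue: float
    q_cov: float
    s_cov: float

    def __post_init__(self):
        if not (0.0 <= self.q_cov <= 1.0 and 0.0 <= self.s_cov <= 1.0):
            raise ValueError(
                f"coverage outside [0,1] for hit {self.query!r}->{self.subject!r}"
            )
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.query!r}->{self.subject!r}")


@dataclass(frozen=True)
class GeneStructure:
    """Exon-intron architecture of one gene in coding-sequence space.

    ``introns`` are 0-based offsets: the number of coding nucleotides
    5' of the intron.  Phase is ``offset % 3``.
    """

    gene_id: str
    species_id: str
    cds_length: int
    introns: tuple[int, ...] = ()

    def __post_init__(self):
        if self.cds_length <= 0:
            raise ValueError(f"gene {self.gene_id!r}: cds_length must be positive")
        prev = 0
        for off in self.introns:
            if not (0 < off < self.cds_length):
                raise ValueError(
                    f"gene {self.gene_id!r}: intron offset {off} outside "
                    f"(0, {self.cds_length})"
                )
            if off <= prev and prev != 0:
                raise ValueError(
                    f"gene {self.gene_id!r}: intron offsets must strictly increase"
                )
            prev = off

    def phases(self) -> list[int]:
        return [off % 3 for off in self.introns]


class PhyleticMatrix:
    """Binary families x species presence/absence matrix.

    Backed by a pandas DataFrame (index = family ids, columns = species
    ids, values = 0/1 int8); row and column order is meaningful and
    preserved on round-trip.
    """

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(
                f"matrix cell at family {frame.index[bad[0]]!r}, species "
                f"{frame.columns[bad[1]]!r} is not 0/1"
            )
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise ValueError("duplicate family or species ids in matrix")
        self.frame = frame.astype(np.int8)

    @classmethod
    def from_arrays(cls, family_ids, species_ids, cells) -> "PhyleticMatrix":
        return cls(pd.DataFrame(np.asarray(cells), index=list(family_ids),
                                columns=list(species_ids)))

    @property
    def family_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def profile(self, family_id: str) -> dict[str, int]:
        return {s: int(v) for s, v in self.frame.loc[family_id].items()}

    def __eq__(self, other):
        return isinstance(other, PhyleticMatrix) and self.frame.equals(other.frame)

    def __repr__(self):  # pragma: no cover
        return f"PhyleticMatrix({self.frame.shape[0]} families x {self.frame.shape[1]} species)"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: str | None = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (order preserved).

    The first whitespace-delimited token of each header is the seq_id.
    ``alphabet`` of ``"protein"`` restricts residues to the 20 standard
    letters plus X; ``"dna"`` to ACGTN; ``None`` skips the check.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ValueError(f"duplicate seq_id {rec.id!r} in {path}")
        seen.add(rec.id)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        if alphabet == "protein":
            bad = set(seq) - PROTEIN_ALPHABET
            if bad:
                raise ValueError(
                    f"record {rec.id!r}: non-protein characters {sorted(bad)}"
                )
        elif alphabet == "dna":
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"record {rec.id!r}: non-DNA characters {sorted(bad)}"
                )
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_metadata(path) -> list[GenomeMeta]:
    """Read the sidecar metadata TSV (seq_id, genome_id, compartment, taxon_path)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["seq_id", "genome_id", "compartment", "taxon_path"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"metadata {path} lacks columns {missing}")
    if table["seq_id"].duplicated().any():
        dup = table.loc[table["seq_id"].duplicated(), "seq_id"].iloc[0]
        raise ValueError(f"seq_id {dup!r} appears more than once in {path}")
    rows = []
    for _, row in table.iterrows():
        rows.append(GenomeMeta(
            seq_id=row["seq_id"],
            genome_id=row["genome_id"],
            compartment=row["compartment"],
            taxon_path=tuple(str(row["taxon_path"]).split(";")),
        ))
    return rows


def write_metadata(meta, path) -> None:
    frame = pd.DataFrame(
        [(m.seq_id, m.genome_id, m.compartment, ";".join(m.taxon_path))
         for m in meta],
        columns=["seq_id", "genome_id", "compartment", "taxon_path"],
    )
    frame.to_csv(path, sep="\t", index=False)


_BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
]


def read_blast_tab(path) -> list[SimilarityHit]:
    """Read BLAST tabular hits in the ``6 std qlen slen`` 14-column dialect.

    Coverage is computed from the HSP span of the row itself:
    (qend - qstart + 1)/qlen for the query and likewise for the subject.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 14:
                raise ValueError(
                    f"{path}:{lineno}: expected 14 tab-separated columns "
                    f"(outfmt '6 std qlen slen'), got {len(parts)}"
                )
            row = dict(zip(_BLAST_COLUMNS, parts))
            qlen, slen = int(row["qlen"]), int(row["slen"])
            if qlen <= 0 or slen <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive qlen/slen")
            qspan = abs(int(row["qend"]) - int(row["qstart"])) + 1
            sspan = abs(int(row["send"]) - int(row["sstart"])) + 1
            hits.append(SimilarityHit(
                query=row["qseqid"],
                subject=row["sseqid"],
                score=float(row["bitscore"]),
                evalue=float(row["evalue"]),
                q_cov=min(1.0, qspan / qlen),
                s_cov=min(1.0, sspan / slen),
            ))
    return hits


def read_newick(path) -> RootedTree:
    text = Path(path).read_text()
    return RootedTree.from_newick(text)


def write_newick(tree: RootedTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def read_matrix_tsv(path) -> PhyleticMatrix:
    """Read a families x species 0/1 matrix TSV (first column = family ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_rows = bool(fh.readline())
    if not has_rows:  # header-only file: zero families is a valid matrix
        return PhyleticMatrix(pd.DataFrame(columns=header[1:], dtype=np.int8))
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    cells = np.empty(frame.shape, dtype=np.int8)
    for i, fam in enumerate(frame.index):
        for j, sp in enumerate(frame.columns):
            v = frame.iat[i, j]
            if v not in ("0", "1"):
                raise ValueError(
                    f"{path}: cell at family {fam!r}, species {sp!r} is {v!r}, "
                    "expected 0 or 1"
                )
            cells[i, j] = int(v)
    return PhyleticMatrix.from_arrays(frame.index, frame.columns, cells)


def write_matrix_tsv(matrix: PhyleticMatrix, path) -> None:
    matrix.frame.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GFF3 gene structures
# ---------------------------------------------------------------------------

def read_gff3_structures(gff_path, cds_fasta_path,
                         species_map: dict[str, str] | None = None,
                         ) -> list[GeneStructure]:
    """Extract exon-intron architectures from GFF3 CDS features.

    CDS features sharing a ``Parent`` attribute form one gene.  Segments
    are sorted into transcription order (reverse genomic order on the
    minus strand) and intron positions are emitted as 0-based offsets
    into the spliced coding sequence.  The summed exon length must match
    the length of the gene's entry in the CDS FASTA.

    A ``species`` attribute on the CDS features, or ``species_map``,
    supplies the species id (the map wins); otherwise it is empty.
    """
    cds_records = {r.seq_id: r for r in read_fasta(cds_fasta_path, alphabet=None)}
    genes: dict[str, list[tuple[int, int, str]]] = {}
    species_attr: dict[str, str] = {}
    order: list[str] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "CDS":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            parent = attr.get("Parent") or attr.get("ID")
            if parent is None:
                raise ValueError(f"{gff_path}:{lineno}: CDS without Parent/ID")
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{gff_path}:{lineno}: end < start")
            if parent not in genes:
                genes[parent] = []
                order.append(parent)
            genes[parent].append((start_i, end_i, strand))
            if "species" in attr:
                species_attr[parent] = attr["species"]

    structures = []
    for gene_id in order:
        segs = sorted(genes[gene_id])
        strands = {s for _, _, s in segs}
        if len(strands) > 1:
            raise ValueError(f"gene {gene_id!r}: CDS segments on mixed strands")
        for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {gene_id!r}: overlapping CDS segments")
        strand = strands.pop()
        if strand == "-":
            segs = segs[::-1]  # transcription order: 3'-most genomic first
        lengths = [e - s + 1 for s, e, _ in segs]
        total = sum(lengths)
        if gene_id not in cds_records:
            raise ValueError(f"gene {gene_id!r}: no entry in CDS FASTA")
        cds_len = cds_records[gene_id].length
        if total != cds_len:
            raise ValueError(
                f"gene {gene_id!r}: exon lengths sum to {total} but CDS "
                f"FASTA length is {cds_len}"
            )
        offsets = tuple(np.cumsum(lengths[:-1]).tolist())
        species = (species_map or {}).get(gene_id, species_attr.get(gene_id, ""))
        structures.append(GeneStructure(
            gene_id=gene_id, species_id=species,
            cds_length=total, introns=offsets,
        ))
    return structures
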