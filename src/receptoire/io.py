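"""Readers and writers for the external formats the pipeline consumes.

Formats: protein FASTA (proteomes and reference panels), HMMER ``--domtblout``
per-domain tables and a simplified TSV dialect with the same information,
tmhmm-style transmembrane summary tables, GFF3 gene coordinates, and Newick
species trees.  All coordinates are 1-based inclusive internally (the GFF3 and
HMMER convention).  Also provides primary-transcript selection (one protein
per gene) and a built-in hydropathy-based transmembrane-helix fallback for
proteomes without a precomputed tmhmm table.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "DomainHit",
    "TmRecord",
    "GeneLocus",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_domain_hits",
    "write_domain_hits",
    "read_tm_table",
    "write_tm_table",
    "predict_tm_helices",
    "read_gff_genes",
    "write_gff_genes",
    "read_newick",
    "patristic_distances",
    "select_primary_transcripts",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


_INF = float("inf")


# Amino-acid alphabet tolerated in input proteomes: the 20 standard residues
# plus ambiguity/selenocysteine/stop codes commonly present in annotations.
_AA_OK = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
_AA_BAD = re.compile(r"[^ACDEFGHIKLMNPQRSTVWYXBZJUO*acdefghiklmnpqrstvwyxbzjuo]")


@dataclass(frozen=True)
class ProteinRecord:
    """One primary-transcript protein sequence."""

    protein_id: str
    gene_id: str
    species_id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise FormatError(f"empty sequence for protein {self.protein_id!r}")
        m = _AA_BAD.search(self.sequence)
        if m:
            raise FormatError(
                f"protein {self.protein_id!r}: non-amino-acid character {m.group()!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein (one row of a per-domain table)."""

    protein_id: str
    pfam_acc: str
    seq_evalue: float
    dom_evalue: float
    bitscore: float
    ali_start: int
    ali_end: int
    env_start: int
    env_end: int
    #: accession with the version suffix stripped (PF00069.26 -> PF00069);
    #: precomputed because classification rules compare it constantly
    pfam_base: str = field(init=False)

    def __post_init__(self):
        if not (1 <= self.ali_start <= self.ali_end):
            raise FormatError(
                f"hit on {self.protein_id!r}: bad alignment coords "
                f"{self.ali_start}..{self.ali_end}"
            )
        if self.seq_evalue < 0 or self.dom_evalue < 0:
            raise FormatError(f"hit on {self.protein_id!r}: negative E-value")
        if self.bitscore != self.bitscore or self.bitscore in (_INF, -_INF):
            raise FormatError(f"hit on {self.protein_id!r}: non-finite bit score")
        object.__setattr__(self, "pfam_base", self.pfam_acc.split(".", 1)[0])

    @property
    def ali_length(self) -> int:
        """Alignment length in residues (1-based inclusive coordinates)."""
        return self.ali_end - self.ali_start + 1


@dataclass(frozen=True)
class TmRecord:
    """Predicted transmembrane-helix count for one protein."""

    protein_id: str
    n_helices: int

    def __post_init__(self):
        if self.n_helices < 0:
            raise FormatError(f"{self.protein_id!r}: negative helix count")


@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of a gene, 1-based inclusive."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: bad interval {self.start}..{self.end}"
            )


# ---------------------------------------------------------------------------
# FASTA


def _parse_fasta_header(header: str, species_id: str) -> tuple[str, str]:
    """Extract (protein_id, gene_id) from a FASTA description line.

    gene_id comes from a ``gene=`` or ``gene:`` key if present, otherwise from
    the common ``<gene>.<isoform-number>`` naming convention, otherwise it
    equals the protein id.
    """
    fields = header.split()
    protein_id = fields[0]
    m = re.search(r"gene[=:]([^\s;]+)", header)
    if m:
        return protein_id, m.group(1)
    m = re.fullmatch(r"(.+)\.(\d+)", protein_id)
    if m:
        return protein_id, m.group(1)
    return protein_id, protein_id


def read_fasta(path, species_id: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Multi-line sequences are concatenated; input order is preserved.  The
    gene id is parsed from the header (``gene=`` key or trailing isoform
    suffix) and defaults to the protein id.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        protein_id, gene_id = _parse_fasta_header(rec.description, species_id)
        records.append(
            ProteinRecord(
                protein_id=protein_id,
                gene_id=gene_id,
                species_id=species_id,
                sequence=seq,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=f"gene={r.gene_id}")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Domain-hit tables

SIMPLE_TSV_COLUMNS = (
    "protein_id",
    "pfam_acc",
    "seq_evalue",
    "dom_evalue",
    "bitscore",
    "ali_start",
    "ali_end",
    "env_start",
    "env_end",
)

#: Column indices of interest in HMMER 3.x ``--domtblout`` output
#: (whitespace-separated; description field may contain spaces and is last).
_DOMTBL_MIN_COLS = 23


def _hit_from_simple_row(row: Sequence[str], lineno: int) -> DomainHit:
    if len(row) != len(SIMPLE_TSV_COLUMNS):
        raise FormatError(
            f"line {lineno}: expected {len(SIMPLE_TSV_COLUMNS)} columns, "
            f"got {len(row)}"
        )
    try:
        return DomainHit(
            protein_id=row[0],
            pfam_acc=row[1],
            seq_evalue=float(row[2]),
            dom_evalue=float(row[3]),
            bitscore=float(row[4]),
            ali_start=int(row[5]),
            ali_end=int(row[6]),
            env_start=int(row[7]),
            env_end=int(row[8]),
        )
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def _hit_from_domtbl_row(parts: Sequence[str], lineno: int) -> DomainHit:
    if len(parts) < _DOMTBL_MIN_COLS:
        raise FormatError(
            f"line {lineno}: expected >= {_DOMTBL_MIN_COLS} columns in "
            f"domtblout row, got {len(parts)}"
        )
    try:
        # domtblout layout: target name, target acc, tlen, query name,
        # query acc, qlen, full-sequence E-value/score/bias, domain #, of,
        # c-Evalue, i-Evalue, domain score/bias, hmm from/to, ali from/to,
        # env from/to, acc, description.  The target is the protein, the
        # query the Pfam profile (hmmsearch convention).
        return DomainHit(
            protein_id=parts[0],
            pfam_acc=parts[4] if parts[4] != "-" else parts[3],
            seq_evalue=float(parts[6]),
            dom_evalue=float(parts[12]),
            bitscore=float(parts[7]),
            ali_start=int(parts[17]),
            ali_end=int(parts[18]),
            env_start=int(parts[19]),
            env_end=int(parts[20]),
        )
    except ValueError as exc:
        raise FormatError(f"line {lineno}: {exc}") from exc


def read_domain_hits(path, dialect: str = "simple-tsv") -> list[DomainHit]:
    """Read a per-domain hit table.

    Parameters
    ----------
    dialect:
        ``"hmmer-domtbl"`` for HMMER 3.x ``--domtblout`` output (one row per
        domain, ``#`` comment lines skipped) or ``"simple-tsv"`` for the
        package's 9-column tab-separated dialect (see
        :data:`SIMPLE_TSV_COLUMNS`; an optional header row is recognised).
    """
    if dialect not in ("hmmer-domtbl", "simple-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "hmmer-domtbl":
                hits.append(_hit_from_domtbl_row(line.split(), lineno))
            else:
                row = line.split("\t")
                if lineno == 1 and row[0] == "protein_id":
                    continue
                hits.append(_hit_from_simple_row(row, lineno))
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path) -> None:
    """Write hits in the simple-tsv dialect (with header row)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SIMPLE_TSV_COLUMNS)
        for h in hits:
            writer.writerow(
                [
                    h.protein_id,
                    h.pfam_acc,
                    repr(h.seq_evalue),
                    repr(h.dom_evalue),
                    repr(h.bitscore),
                    h.ali_start,
                    h.ali_end,
                    h.env_start,
                    h.env_end,
                ]
            )


# ---------------------------------------------------------------------------
# Transmembrane tables and fallback predictor


def read_tm_table(path) -> dict[str, TmRecord]:
    """Read a tmhmm-style summary table: protein_id <tab> n_helices.

    Also accepts tmhmm's short-format lines where the helix count appears as
    a ``PredHel=N`` field.
    """
    out: dict[str, TmRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "protein_id":
                continue
            pid = parts[0]
            m = re.search(r"PredHel=(\d+)", line)
            if m:
                n = int(m.group(1))
            elif len(parts) >= 2:
                try:
                    n = int(parts[1])
                except ValueError as exc:
                    raise FormatError(f"line {lineno}: {exc}") from exc
            else:
                raise FormatError(f"line {lineno}: no helix count found")
            out[pid] = TmRecord(protein_id=pid, n_helices=n)
    return out


def write_tm_table(records: Iterable[TmRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("protein_id\tn_helices\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.n_helices}\n")


#: Kyte-Doolittle hydropathy scale; ambiguity codes get neutral 0.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def predict_tm_helices(
    sequence: str, window: int = 19, threshold: float = 1.6
) -> int:
    """Sliding-window Kyte-Doolittle transmembrane-helix count.

    A window of `window` residues with mean hydropathy above `threshold`
    marks a membrane-spanning segment; contiguous runs of qualifying windows
    are merged into one helix.  This is a coarse fallback for proteomes
    without a precomputed tmhmm table — adequate for synthetic data and
    rough screening, not a replacement for a dedicated TM predictor.
    """
    if len(sequence) < window:
        return 0
    h = np.array([_KD.get(aa, 0.0) for aa in sequence.upper()])
    means = np.convolve(h, np.ones(window) / window, mode="valid")
    above = means > threshold
    # count runs of consecutive qualifying windows
    return int(np.sum(above[1:] & ~above[:-1]) + (1 if above[0] else 0))


# ---------------------------------------------------------------------------
# GFF3 gene coordinates

_GFF_COLS = 9


def read_gff_genes(path, feature_type: str = "gene") -> list[GeneLocus]:
    """Read loci of one feature type from a GFF3 file.

    The gene id is taken from the ``ID=`` attribute (``Name=`` as fallback,
    then a synthesized ``<seqid>:<start>-<end>`` label).  Coordinates are kept
    1-based inclusive as in the file.
    """
    loci: list[GeneLocus] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise FormatError(
                    f"line {lineno}: expected {_GFF_COLS} GFF3 columns, "
                    f"got {len(parts)}"
                )
            if parts[2] != feature_type:
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if start > end:
                raise FormatError(f"line {lineno}: start {start} > end {end}")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or (
                f"{parts[0]}:{start}-{end}"
            )
            strand = parts[6] if parts[6] in "+-" else "?"
            loci.append(
                GeneLocus(
                    gene_id=gene_id,
                    seq_id=parts[0],
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    return loci


def write_gff_genes(loci: Iterable[GeneLocus], path, source: str = "receptoire") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in loci:
            strand = g.strand if g.strand in "+-" else "."
            fh.write(
                f"{g.seq_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Species tree


def read_newick(path) -> dendropy.Tree:
    """Read a Newick species tree (leaf labels = species ids)."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    return tree


def patristic_distances(tree: dendropy.Tree, labels: Sequence[str]):
    """Leaf-to-leaf path-length (patristic) distance matrix.

    Returns a :class:`receptoire.phylo.DistanceMatrix` restricted and ordered
    to `labels`.  Unknown labels raise ``KeyError`` listing every missing one.
    """
    from receptoire.phylo import DistanceMatrix  # avoid import cycle

    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [lb for lb in labels if lb not in taxa]
    if missing:
        raise KeyError(f"labels absent from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=list(labels), values=mat, tag="phylogeny")


# ---------------------------------------------------------------------------
# Primary transcripts


def select_primary_transcripts(
    proteins: Sequence[ProteinRecord],
) -> list[ProteinRecord]:
    """Keep one protein per gene: the longest isoform.

    Ties are broken by lexicographically smallest protein id, so the result
    is deterministic and independent of input order.  Proteins whose gene id
    equals their protein id (no gene mapping available) are each treated as
    their own gene.  Output follows the first-seen order of gene ids.
    """
    if any(p.gene_id == p.protein_id for p in proteins) and any(
        p.gene_id != p.protein_id for p in proteins
    ):
        logger.warning(
            "mixed gene-id provenance: some proteins lack a gene mapping and "
            "are treated as single-isoform genes"
        )
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for p in proteins:
        cur = best.get(p.gene_id)
        if cur is None:
            best[p.gene_id] = p
            order.append(p.gene_id)
        elif (p.length, _neg_lex(p.protein_id)) > (cur.length, _neg_lex(cur.protein_id)):
            best[p.gene_id] = p
    # order-independence: sort output by gene id for a canonical order
    return [best[g] for g in sorted(order)]


class _neg_lex(str):
    """String wrapper inverting lexicographic order (for max-with-min-tiebreak)."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)
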