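"""Domain types and readers/writers shared by the whole pipeline.

All genomic coordinates are 0-based, half-open, on an explicit strand.
Minus-strand precursor sequences are stored reverse-complemented, i.e. in
transcript orientation, so that every downstream interval computation is in
transcript space.  The internal alphabet is DNA (``U`` is converted to ``T``
on input); renderers may emit ``U`` again.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


class FormatError(ValueError):
    """A record parsed but violates the declared format convention."""


class StructureError(ValueError):
    """A tree (or other structured input) is malformed for this pipeline."""


class ContractError(ValueError):
    """A function precondition was violated by the caller."""


class ConfigurationError(ValueError):
    """An analysis was configured inconsistently (e.g. no control library)."""


_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CONTROL = "control"
DICER_DEPLETED = "dicer_depleted"


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA ``U`` to DNA ``T``."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def as_rna(seq: str) -> str:
    """Render an internal DNA string as RNA (for display only)."""
    return seq.replace("T", "U")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """A named contig/scaffold over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ContractError(f"sequence {self.id!r} is empty")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ContractError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Locus:
    """A stranded genomic interval, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ContractError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ContractError(f"empty/inverted interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ContractError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Locus") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Locus") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def validate_against(self, genome: Mapping[str, GenomeSequence]) -> None:
        """Raise :class:`ContractError` if the locus falls outside its contig."""
        if self.seq_id not in genome:
            raise ContractError(f"unknown sequence id {self.seq_id!r}")
        if self.end > len(genome[self.seq_id]):
            raise ContractError(
                f"locus [{self.start},{self.end}) exceeds contig "
                f"{self.seq_id!r} of length {len(genome[self.seq_id])}"
            )


@dataclass(frozen=True)
class ReadRecord:
    """A collapsed small-RNA read: one sequence with its multiplicity."""

    sequence: str
    count: int
    library_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ContractError(f"read count {self.count} < 1")
        if not 16 <= len(self.sequence) <= 30:
            raise ContractError(
                f"read length {len(self.sequence)} outside the 16-30 nt window"
            )


@dataclass(frozen=True)
class Library:
    """A sequencing library with its condition label and RPM denominator."""

    id: str
    condition: str
    total_mapped_reads: int

    def __post_init__(self) -> None:
        if self.condition not in (CONTROL, DICER_DEPLETED):
            raise ContractError(
                f"condition must be {CONTROL!r} or {DICER_DEPLETED!r}, "
                f"got {self.condition!r}"
            )
        if self.total_mapped_reads < 0:
            raise ContractError("total_mapped_reads < 0")


@dataclass(frozen=True)
class MiRNACandidate:
    """A precursor locus with its 5p/3p arm intervals.

    ``precursor_seq`` is in transcript orientation.  Arm loci are genomic
    (strand matching the precursor); :meth:`arm_interval` converts them into
    precursor-relative transcript coordinates.
    """

    id: str
    precursor_locus: Locus
    precursor_seq: str
    arm5p_locus: Locus
    arm3p_locus: Locus
    source_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name, arm in (("5p", self.arm5p_locus), ("3p", self.arm3p_locus)):
            if not self.precursor_locus.contains(arm):
                raise ContractError(
                    f"{self.id}: {name} arm not contained in precursor locus"
                )
        if self.arm5p_locus.overlaps(self.arm3p_locus):
            raise ContractError(f"{self.id}: arms overlap")
        if len(self.precursor_seq) != len(self.precursor_locus):
            raise ContractError(
                f"{self.id}: precursor_seq length does not match its locus"
            )

    def arm_interval(self, arm: str) -> tuple[int, int]:
        """Precursor-relative, transcript-oriented [start, end) of an arm."""
        locus = {"5p": self.arm5p_locus, "3p": self.arm3p_locus}[arm]
        p = self.precursor_locus
        if p.strand == "+":
            return locus.start - p.start, locus.end - p.start
        return p.end - locus.end, p.end - locus.start

    def arm_seq(self, arm: str) -> str:
        s, e = self.arm_interval(arm)
        return self.precursor_seq[s:e]

    def validate_against(self, genome: Mapping[str, GenomeSequence]) -> None:
        """Check the precursor sequence matches the genome, strand-aware."""
        self.precursor_locus.validate_against(genome)
        expected = extract_locus_sequence(genome, self.precursor_locus)
        if expected != self.precursor_seq:
            raise ContractError(
                f"{self.id}: precursor_seq does not match the genome at "
                f"{self.precursor_locus}"
            )


@dataclass(frozen=True)
class MiRNAGene:
    """A curated miRNA gene with its mature/star sequences and family."""

    name: str
    family: str
    mature_seq: str
    star_seq: str
    mature_arm: str  # {5p, 3p, co-mature}
    conservation: str  # {conserved, specific}

    def __post_init__(self) -> None:
        if not 18 <= len(self.mature_seq) <= 30:
            raise ContractError(
                f"{self.name}: mature length {len(self.mature_seq)} outside [18,30]"
            )
        if self.mature_arm not in ("5p", "3p", "co-mature"):
            raise ContractError(f"{self.name}: invalid mature_arm {self.mature_arm!r}")
        if self.conservation not in ("conserved", "specific"):
            raise ContractError(
                f"{self.name}: invalid conservation {self.conservation!r}"
            )


def extract_locus_sequence(
    genome: Mapping[str, GenomeSequence], locus: Locus
) -> str:
    """Transcript-oriented sequence of ``locus`` (reverse-complemented on '-')."""
    locus.validate_against(genome)
    raw = genome[locus.seq_id].sequence[locus.start : locus.end]
    return reverse_complement(raw) if locus.strand == "-" else raw


def genome_dict(sequences: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    out: dict[str, GenomeSequence] = {}
    for s in sequences:
        if s.id in out:
            raise FormatError(f"duplicate sequence id {s.id!r}")
        out[s.id] = s
    return out


# ---------------------------------------------------------------------------
# Sequence files
# ---------------------------------------------------------------------------

_COLLAPSED_COUNT = re.compile(r"(?:^|[_-])x(\d+)$")


def read_sequences(
    path: str | Path,
    format: str = "fasta",
    library_id: str | None = None,
):
    """Read sequences from ``path``.

    Parameters
    ----------
    format:
        ``fasta`` returns :class:`GenomeSequence` records; ``fastq`` and
        ``collapsed_fasta`` return :class:`ReadRecord`.  Collapsed-FASTA
        headers must end in an ``_x<count>`` token (e.g. ``>r1_x12``).
    library_id:
        Library the reads belong to (required for read formats).
    """
    path = Path(path)
    if format not in ("fasta", "fastq", "collapsed_fasta"):
        raise ConfigurationError(f"unknown sequence format {format!r}")
    bio_format = "fastq" if format == "fastq" else "fasta"
    try:
        records = list(SeqIO.parse(str(path), bio_format))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if format == "fasta":
        return [
            GenomeSequence(id=r.id, sequence=normalize_sequence(str(r.seq)))
            for r in records
        ]
    if library_id is None:
        raise ConfigurationError("library_id is required for read formats")
    out: list[ReadRecord] = []
    for r in records:
        seq = normalize_sequence(str(r.seq))
        if format == "collapsed_fasta":
            m = _COLLAPSED_COUNT.search(r.id)
            if not m:
                raise FormatError(
                    f"{path}: header {r.id!r} lacks a trailing _x<count> token"
                )
            count = int(m.group(1))
        else:
            count = 1
        out.append(ReadRecord(sequence=seq, count=count, library_id=library_id))
    return out


def write_fasta(records, path: str | Path, as_rna_alphabet: bool = False) -> None:
    """Write :class:`GenomeSequence`-like records (``.id``/``.sequence``)."""
    with open(path, "w") as fh:
        for rec in records:
            seq = as_rna(rec.sequence) if as_rna_alphabet else rec.sequence
            fh.write(f">{rec.id}\n{seq}\n")


def write_collapsed_fasta(reads: Sequence[ReadRecord], path: str | Path) -> None:
    """Write reads in collapsed-FASTA form, re-aggregating identical sequences."""
    totals: dict[str, int] = {}
    for r in reads:
        totals[r.sequence] = totals.get(r.sequence, 0) + r.count
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(totals.items()), start=1):
            fh.write(f">r{i}_x{count}\n{seq}\n")


# ---------------------------------------------------------------------------
# Loci: GFF3 / BED6
# ---------------------------------------------------------------------------


def read_loci_gff3(path: str | Path) -> list[tuple[Locus, dict]]:
    """Read (Locus, attributes) pairs from GFF3 (1-based closed -> half-open)."""
    out: list[tuple[Locus, dict]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seq_id, _src, _type, start, end, _score, strand, _phase, attrs = fields
            try:
                locus = Locus(seq_id, int(start) - 1, int(end), strand)
            except (ValueError, ContractError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            attributes = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attributes[k.strip()] = v.strip()
            out.append((locus, attributes))
    return out


def write_loci_gff3(
    loci: Sequence[tuple[Locus, Mapping[str, str]]],
    path: str | Path,
    source: str = "mircurate",
    feature_type: str = "miRNA_primary_transcript",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus, attrs in loci:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{locus.seq_id}\t{source}\t{feature_type}\t{locus.start + 1}\t"
                f"{locus.end}\t.\t{locus.strand}\t.\t{attr_str}\n"
            )


def read_loci_bed6(path: str | Path) -> list[tuple[Locus, str]]:
    """Read (Locus, name) pairs from BED6 (already 0-based half-open)."""
    out: list[tuple[Locus, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >=6 BED columns")
            try:
                locus = Locus(fields[0], int(fields[1]), int(fields[2]), fields[5])
            except (ValueError, ContractError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append((locus, fields[3]))
    return out


def write_loci_bed6(
    loci: Sequence[tuple[Locus, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for locus, name in loci:
            fh.write(
                f"{locus.seq_id}\t{locus.start}\t{locus.end}\t{name}\t0\t"
                f"{locus.strand}\n"
            )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted newick string; see :func:`read_tree`."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise StructureError(f"malformed newick: {exc}") from exc
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise StructureError("duplicate leaf names in tree")
    if not leaves:
        raise StructureError("tree has no named leaves")
    n_children = len(tree.seed_node.child_nodes())
    if n_children > 2:
        raise StructureError(
            f"root has {n_children} children; an unrooted (basal multifurcation)"
            " tree is not accepted"
        )
    tree.is_rooted = True
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted species tree (newick, unique named leaves)."""
    with open(path) as fh:
        return parse_tree(fh.read())


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def tree_leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [l.taxon.label for l in tree.leaf_node_iter()]


def tree_n_edges(tree: dendropy.Tree) -> int:
    """Number of edges (each non-root node contributes its parent edge)."""
    return sum(1 for n in tree.preorder_node_iter() if n.parent_node is not None)


# ---------------------------------------------------------------------------
# Libraries TSV
# ---------------------------------------------------------------------------


def read_libraries_tsv(path: str | Path) -> list[Library]:
    libs: list[Library] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["library_id", "condition", "total_mapped_reads"]:
            raise FormatError(f"{path}: unexpected libraries header {header}")
        for line in fh:
            if not line.strip():
                continue
            lid, cond, total = line.rstrip("\n").split("\t")[:3]
            libs.append(Library(lid, cond, int(total)))
    return libs


def write_libraries_tsv(libraries: Sequence[Library], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\tcondition\ttotal_mapped_reads\n")
        for lib in libraries:
            fh.write(f"{lib.id}\t{lib.condition}\t{lib.total_mapped_reads}\n")


# ---------------------------------------------------------------------------
# Candidate sets (GFF3 with precursor + arm features)
# ---------------------------------------------------------------------------


def write_candidates_gff3(
    candidates: Sequence[MiRNACandidate], path: str | Path, extra: Mapping[str, Mapping[str, str]] | None = None
) -> None:
    """Write candidates as GFF3: one precursor line plus two arm lines each.

    ``extra`` optionally maps candidate id to additional attributes for the
    precursor line (e.g. synthetic truth labels).
    """
    rows: list[tuple[Locus, dict]] = []
    for c in candidates:
        attrs = {"ID": c.id}
        if c.source_tags:
            attrs["source_tags"] = ",".join(sorted(c.source_tags))
        if extra and c.id in extra:
            attrs.update(extra[c.id])
        rows.append((c.precursor_locus, attrs))
        rows.append((c.arm5p_locus, {"ID": f"{c.id}_5p", "Parent": c.id, "arm": "5p"}))
        rows.append((c.arm3p_locus, {"ID": f"{c.id}_3p", "Parent": c.id, "arm": "3p"}))
    write_loci_gff3(rows, path)


def read_candidates_gff3(
    path: str | Path, genome: Mapping[str, GenomeSequence]
) -> tuple[list[MiRNACandidate], dict[str, dict]]:
    """Read candidates written by :func:`write_candidates_gff3`.

    Precursor sequences are re-extracted from ``genome`` (strand-aware).
    Returns the candidates and the precursor-line attributes by id.
    """
    entries = read_loci_gff3(path)
    precursors: dict[str, tuple[Locus, dict]] = {}
    arms: dict[str, dict[str, Locus]] = {}
    for locus, attrs in entries:
        if "Parent" in attrs:
            arms.setdefault(attrs["Parent"], {})[attrs.get("arm", "?")] = locus
        else:
            precursors[attrs["ID"]] = (locus, attrs)
    candidates = []
    attributes = {}
    for cid, (locus, attrs) in precursors.items():
        arm_pair = arms.get(cid, {})
        if "5p" not in arm_pair or "3p" not in arm_pair:
            raise FormatError(f"{path}: candidate {cid} lacks 5p/3p arm lines")
        tags = frozenset(
            t for t in attrs.get("source_tags", "").split(",") if t
        )
        candidates.append(
            MiRNACandidate(
                id=cid,
                precursor_locus=locus,
                precursor_seq=extract_locus_sequence(genome, locus),
                arm5p_locus=arm_pair["5p"],
                arm3p_locus=arm_pair["3p"],
                source_tags=tags,
            )
        )
        attributes[cid] = attrs
    return candidates, attributes
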