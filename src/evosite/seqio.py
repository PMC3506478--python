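"""Alignment I/O, codon-alignment validation, trimming and reference-coordinate maps.

Coordinates are 1-based and closed-interval throughout.  Trimming keeps an
``origin_offset`` on the result so downstream site numbers always refer to the
original (untrimmed) numbering of the reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data import CodonTable

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"

_PROTEIN_SYMBOLS = set("ACDEFGHIKLMNPQRSTVWY") | {"-", "X"}
_NUCLEOTIDE_SYMBOLS = set("ACGT") | {"-", "N"}

#: 61 sense codons of the standard genetic code, lexicographic order.
_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_standard.stop_codons))
SENSE_CODONS = tuple(sorted(_standard.forward_table))
CODON_TO_AA = dict(_standard.forward_table)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


class AlignmentError(ValueError):
    """Raised for malformed alignments or codon-frame violations."""


@dataclass
class MultipleAlignment:
    """An aligned set of sequences over a declared alphabet.

    ``records`` preserves input order; identifiers are unique; all rows have
    equal length ``n_columns``.
    """

    records: list[tuple[str, str]]
    alphabet: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        if self.alphabet not in (PROTEIN, NUCLEOTIDE):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")
        if not self.records:
            raise AlignmentError("empty alignment")
        lengths = {len(row) for _, row in self.records}
        if len(lengths) != 1:
            bad = [rid for rid, row in self.records
                   if len(row) != len(self.records[0][1])]
            raise AlignmentError(
                f"unequal row lengths (offending identifiers: {', '.join(bad)})")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate identifiers: {', '.join(dupes)}")
        legal = _PROTEIN_SYMBOLS if self.alphabet == PROTEIN else _NUCLEOTIDE_SYMBOLS
        for rid, row in self.records:
            for pos, sym in enumerate(row, start=1):
                if sym not in legal:
                    raise AlignmentError(
                        f"illegal symbol {sym!r} in {rid!r} at column {pos}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @property
    def identifiers(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, identifier: str) -> str:
        for rid, row in self.records:
            if rid == identifier:
                return row
        raise KeyError(identifier)

    def column(self, col: int) -> str:
        """Symbols of 1-based column ``col``, in record order."""
        return "".join(row[col - 1] for _, row in self.records)

    def subset(self, identifiers: list[str]) -> "MultipleAlignment":
        keep = set(identifiers)
        recs = [(rid, row) for rid, row in self.records if rid in keep]
        missing = keep - {rid for rid, _ in recs}
        if missing:
            raise KeyError(f"identifiers not in alignment: {sorted(missing)}")
        return MultipleAlignment(recs, self.alphabet, self.origin_offset)


@dataclass
class CodonAlignment:
    """Codon-resolved view of an in-frame nucleotide alignment."""

    base: MultipleAlignment
    genetic_code: dict = field(default_factory=lambda: dict(CODON_TO_AA))

    def __post_init__(self) -> None:
        aln = self.base
        if aln.alphabet != NUCLEOTIDE:
            raise AlignmentError("codon alignment requires nucleotide alphabet")
        if aln.n_columns % 3 != 0:
            raise AlignmentError(
                f"alignment length {aln.n_columns} not divisible by 3")
        n_sites = aln.n_columns // 3
        for rid, row in aln.records:
            for k in range(n_sites):
                codon = row[3 * k: 3 * k + 3]
                if "-" in codon:
                    if codon != "---":
                        raise AlignmentError(
                            f"partial-codon gap {codon!r} in {rid!r} at codon {k + 1}")
                    continue
                if "N" in codon:
                    continue
                if codon in STOP_CODONS and k < n_sites - 1:
                    raise AlignmentError(
                        f"internal stop codon {codon!r} in {rid!r} at codon {k + 1}")

    @property
    def n_codon_sites(self) -> int:
        return self.base.n_columns // 3

    @property
    def origin_offset(self) -> int:
        return self.base.origin_offset

    @property
    def identifiers(self) -> list[str]:
        return self.base.identifiers

    def codon(self, identifier: str, site: int) -> str:
        """Codon at 1-based codon site ``site``."""
        row = self.base.row(identifier)
        return row[3 * (site - 1): 3 * (site - 1) + 3]

    def codon_rows(self) -> list[tuple[str, list[str]]]:
        n = self.n_codon_sites
        return [(rid, [row[3 * k: 3 * k + 3] for k in range(n)])
                for rid, row in self.base.records]

    def translate(self) -> MultipleAlignment:
        """Amino-acid view; gap codons become '-', ambiguous codons 'X'."""
        rows = []
        for rid, codons in self.codon_rows():
            aa = []
            for c in codons:
                if c == "---":
                    aa.append("-")
                elif "N" in c or c in STOP_CODONS:
                    aa.append("X")
                else:
                    aa.append(self.genetic_code[c])
            rows.append((rid, "".join(aa)))
        # protein offset counts residues, nucleotide offset counted bp
        return MultipleAlignment(rows, PROTEIN, self.base.origin_offset // 3)


@dataclass
class ReferenceMap:
    """Bidirectional map between alignment columns and ungapped residue numbers
    of a chosen reference row.  Residue numbers include any trim offset."""

    reference_id: str
    column_to_residue: dict[int, int]
    residue_to_column: dict[int, int]

    def residue(self, column: int) -> int | None:
        return self.column_to_residue.get(column)

    def column(self, residue: int) -> int | None:
        return self.residue_to_column.get(residue)


def read_alignment(path, alphabet: str) -> MultipleAlignment:
    """Read a FASTA alignment, validating alphabet and rectangular shape."""
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return MultipleAlignment(records, alphabet)


def write_alignment(aln: MultipleAlignment, path) -> None:
    recs = [SeqRecord(Seq(row), id=rid, description="") for rid, row in aln.records]
    SeqIO.write(recs, str(path), "fasta")


def as_codon_alignment(aln: MultipleAlignment) -> CodonAlignment:
    return CodonAlignment(aln)


def trim_leading(aln, n_units: int):
    """Drop the first ``n_units`` columns (residues or bp), retaining an origin
    offset so that reported coordinates stay in untrimmed numbering."""
    if isinstance(aln, CodonAlignment):
        if n_units % 3 != 0:
            raise AlignmentError("codon trim must be a multiple of 3 bp")
        return CodonAlignment(trim_leading(aln.base, n_units))
    if n_units < 0 or n_units >= aln.n_columns:
        raise AlignmentError(
            f"cannot trim {n_units} columns from alignment of {aln.n_columns}")
    recs = [(rid, row[n_units:]) for rid, row in aln.records]
    return MultipleAlignment(recs, aln.alphabet, aln.origin_offset + n_units)


def build_reference_map(aln: MultipleAlignment, reference_id: str) -> ReferenceMap:
    """Map alignment columns to 1-based ungapped positions of ``reference_id``.

    Residue numbers start at ``origin_offset + 1`` so trimmed alignments report
    original coordinates.
    """
    try:
        ref_row = aln.row(reference_id)
    except KeyError:
        raise AlignmentError(f"unknown reference identifier {reference_id!r}")
    c2r: dict[int, int] = {}
    residue = aln.origin_offset
    for col, sym in enumerate(ref_row, start=1):
        if sym != "-":
            residue += 1
            c2r[col] = residue
    return ReferenceMap(reference_id, c2r, {r: c for c, r in c2r.items()})


def check_leaf_alignment_match(tree, aln: MultipleAlignment) -> None:
    """Raise unless every tree leaf has a row in the alignment."""
    missing = set(tree.leaf_names()) - set(aln.identifiers)
    if missing:
        raise AlignmentError(
            f"tree leaves missing from alignment: {sorted(missing)}")
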