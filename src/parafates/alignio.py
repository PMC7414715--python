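"""Family alignment input, validation, paralog-pair extraction and gap trimming.

A family is a protein multiple sequence alignment (FASTA, '-' gaps) plus a
gene-to-species map (two-column TSV). The analysis unit downstream is the
*paralog pair*: the exactly two family members of one species. Species with a
single copy or with three or more copies contribute no pair and are ignored by
the quartet machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .substmodels import AMINO_ACIDS

GAP = "-"
#: characters normalized to the ambiguity code 'X'
_AMBIGUOUS = set("BZJUO*?")
_ALLOWED = set(AMINO_ACIDS) | {GAP, "X"}


class AlignmentShapeError(ValueError):
    """Sequences of unequal length, or an empty/degenerate alignment."""


class IdentityError(ValueError):
    """Duplicate gene identifiers or conflicting species assignments."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and map ambiguity codes to 'X' ('.' is read as a gap)."""
    out = []
    for ch in seq.upper():
        if ch == ".":
            out.append(GAP)
        elif ch in _AMBIGUOUS:
            out.append("X")
        elif ch in _ALLOWED:
            out.append(ch)
        else:
            raise ValueError(f"unrecognized residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class GeneRecord:
    """One aligned gene: identifier, source species and aligned sequence."""

    gene_id: str
    species_id: str
    aligned_seq: str

    def __post_init__(self):
        if not self.aligned_seq:
            raise AlignmentShapeError(f"empty sequence for gene {self.gene_id}")
        bad = set(self.aligned_seq) - _ALLOWED
        if bad:
            raise ValueError(f"gene {self.gene_id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class ParalogPair:
    """The two copies of a family gene in one species (lexicographic order)."""

    species_id: str
    gene_a: str
    gene_b: str

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise IdentityError(f"paralog pair in {self.species_id} repeats {self.gene_a}")

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


class FamilyAlignment:
    """Validated equal-length alignment of a gene family.

    Residues are also exposed as an integer matrix (``codes``): 0-19 for the
    twenty amino acids in canonical order, -1 for gap or 'X'. Column indices
    are 0-based internally; user-facing outputs are 1-based.
    """

    def __init__(self, records: list[GeneRecord]):
        if not records:
            raise AlignmentShapeError("alignment has no records")
        lengths = {len(r.aligned_seq) for r in records}
        if len(lengths) != 1:
            raise AlignmentShapeError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [r.gene_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise IdentityError(f"duplicate gene ids: {dupes}")
        self.records = list(records)
        self.length = lengths.pop()
        self._index = {r.gene_id: i for i, r in enumerate(self.records)}
        lut = np.full(128, -1, dtype=np.int8)
        for i, aa in enumerate(AMINO_ACIDS):
            lut[ord(aa)] = i
        buf = np.frombuffer(
            "".join(r.aligned_seq for r in self.records).encode(), dtype=np.uint8
        )
        self.codes = lut[buf].reshape(len(self.records), self.length)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def row(self, gene_id: str) -> np.ndarray:
        return self.codes[self._index[gene_id]]

    def record(self, gene_id: str) -> GeneRecord:
        return self.records[self._index[gene_id]]


def read_alignment(path: str | Path) -> FamilyAlignment:
    """Read and validate a FASTA family alignment.

    Lowercase letters are uppercased; ambiguity codes (B, Z, J, U, O, '*', '?')
    become 'X' and '.' becomes a gap.
    """
    seqs = list(SeqIO.parse(str(path), "fasta"))
    if not seqs:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    records = [GeneRecord(s.id, "", normalize_sequence(str(s.seq))) for s in seqs]
    return FamilyAlignment(records)


def write_alignment(aln: FamilyAlignment, path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.aligned_seq), id=r.gene_id, description="") for r in aln.records),
        str(path),
        "fasta",
    )


def read_gene_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping gene_id -> species_id (header optional)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene, species = parts[0].strip(), parts[1].strip()
            if lineno == 1 and gene.lower() in {"gene", "gene_id"}:
                continue
            if gene in mapping and mapping[gene] != species:
                raise IdentityError(
                    f"gene {gene} mapped to both {mapping[gene]} and {species}"
                )
            mapping[gene] = species
    if not mapping:
        raise ValueError(f"empty gene-species map: {path}")
    return mapping


def attach_species(aln: FamilyAlignment, mapping: dict[str, str]) -> FamilyAlignment:
    """Return a copy of the alignment with species ids filled in from the map."""
    missing = [g for g in aln.gene_ids if g not in mapping]
    if missing:
        raise IdentityError(f"genes absent from species map: {missing}")
    return FamilyAlignment(
        [GeneRecord(r.gene_id, mapping[r.gene_id], r.aligned_seq) for r in aln.records]
    )


def extract_paralog_pairs(
    aln: FamilyAlignment, mapping: dict[str, str]
) -> list[ParalogPair]:
    """One pair per species holding exactly two family members.

    Species with one copy (no within-species comparison possible) or with
    three or more copies (additional duplications/losses) yield no pair.
    Order within a pair and across pairs is lexicographic for determinism.
    """
    by_species: dict[str, list[str]] = {}
    for gid in aln.gene_ids:
        if gid not in mapping:
            raise IdentityError(f"gene {gid} absent from species map")
        by_species.setdefault(mapping[gid], []).append(gid)
    pairs = []
    for sp in sorted(by_species):
        genes = sorted(by_species[sp])
        if len(genes) == 2:
            pairs.append(ParalogPair(sp, genes[0], genes[1]))
    return pairs


def trim_gappy_columns(
    aln: FamilyAlignment, max_gap_frac: float = 0.5
) -> tuple[FamilyAlignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_frac``.

    Returns the trimmed alignment and, per retained column, its original
    1-based index. 'X' is not a gap for this purpose.
    """
    if not 0.0 <= max_gap_frac <= 1.0:
        raise ValueError("max_gap_frac must be in [0, 1]")
    cols = np.array(
        [[ch == GAP for ch in r.aligned_seq] for r in aln.records], dtype=bool
    )
    gap_frac = cols.mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_frac)
    if keep.size == 0:
        raise AlignmentShapeError("trimming removed every column")
    trimmed = FamilyAlignment(
        [
            GeneRecord(r.gene_id, r.species_id, "".join(r.aligned_seq[i] for i in keep))
            for r in aln.records
        ]
    )
    return trimmed, [int(i) + 1 for i in keep]
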