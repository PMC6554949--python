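"""Aligned FASTA families: I/O, species de-redundancy, reference coordinates.

An :class:`AlignedFamily` holds one protein family's aligned orthologues.
Every row carries a species identifier parsed from the FASTA header, so that
two families can later be paired species-by-species.  One row per family may
be designated the *reference* sequence (for instance the Arabidopsis
orthologue); :func:`build_column_map` maps aligned columns onto that
sequence's 1-based ungapped residue numbering, which is the coordinate system
in which candidate interface residues are reported.

All coordinates in this package are 1-based, matching standard protein
residue numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids followed by the gap symbol.  The gap is
#: treated as the 21st alphabet state throughout the coevolution analysis.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
GAP = "-"
ALPHABET_SIZE = len(ALPHABET)  # 21

_ALPHABET_SET = frozenset(ALPHABET)


class AlignmentShapeError(ValueError):
    """Rows of an alignment do not all share the same length."""


def default_species_parser(header: str) -> str:
    """Extract the species identifier as the first ``|``-delimited token."""
    return header.split("|")[0]


@dataclass
class FamilyRow:
    species_id: str
    seq_id: str
    residues: str


@dataclass
class AlignedFamily:
    """One protein family's aligned orthologues with species tags.

    Parameters
    ----------
    name
        Family label (e.g. ``"polymerase"`` or ``"twinkle"``).
    rows
        One entry per aligned sequence.  All residue strings have equal
        length and use only :data:`ALPHABET` characters.
    reference_seq_id
        ``seq_id`` of the designated reference row, or ``None``.
    """

    name: str
    rows: list[FamilyRow] = field(default_factory=list)
    reference_seq_id: str | None = None

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"family {self.name!r}: unequal aligned lengths {sorted(lengths)}"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.rows[0].residues) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self.rows]

    def row_by_seq_id(self, seq_id: str) -> FamilyRow:
        for r in self.rows:
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"sequence id {seq_id!r} not found in family {self.name!r}")

    def row_by_species(self, species_id: str) -> FamilyRow:
        for r in self.rows:
            if r.species_id == species_id:
                return r
        raise KeyError(f"species {species_id!r} not found in family {self.name!r}")

    @property
    def reference_row(self) -> FamilyRow:
        if self.reference_seq_id is None:
            raise ValueError(f"family {self.name!r} has no reference sequence set")
        return self.row_by_seq_id(self.reference_seq_id)


def sanitize_residues(residues: str) -> str:
    """Uppercase and remap any non-standard letter to the gap symbol.

    Ambiguity and rare codes (B, Z, X, U, J, O, ``*``, ``.``) have no state
    in the fixed 21-letter model alphabet and are treated as gaps.
    """
    out = []
    for ch in residues.upper():
        out.append(ch if ch in _ALPHABET_SET else GAP)
    return "".join(out)


def read_aligned_fasta(
    path: str | Path,
    name: str | None = None,
    species_parser: Callable[[str], str] = default_species_parser,
    reference_seq_id: str | None = None,
) -> AlignedFamily:
    """Read an aligned protein FASTA file into an :class:`AlignedFamily`.

    Non-standard residue letters are remapped to gaps (see
    :func:`sanitize_residues`).  Raises :class:`AlignmentShapeError` if the
    records are not all the same length, and ``ValueError`` on an empty file.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    rows = [
        FamilyRow(
            species_id=species_parser(rec.id),
            seq_id=rec.id,
            residues=sanitize_residues(str(rec.seq)),
        )
        for rec in records
    ]
    fam = AlignedFamily(
        name=name if name is not None else path.stem,
        rows=rows,
        reference_seq_id=reference_seq_id,
    )
    if reference_seq_id is not None:
        fam.reference_row  # raises KeyError if absent
    return fam


def write_aligned_fasta(fam: AlignedFamily, path: str | Path) -> None:
    """Write an :class:`AlignedFamily` back to aligned FASTA."""
    records = [
        SeqRecord(Seq(r.residues), id=r.seq_id, description="") for r in fam.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def one_per_species_filter(
    fam: AlignedFamily, keep: str | Callable[[list[FamilyRow]], FamilyRow] = "first"
) -> AlignedFamily:
    """Keep a single sequence per species.

    Redundant within-species sequences bias covariance estimates, so the
    coevolution pipeline retains at most one orthologue per species.  The
    default rule keeps the first occurrence in file order; a callable
    receiving all rows of a species may be supplied instead.  Idempotent.
    """
    groups: dict[str, list[FamilyRow]] = {}
    order: list[str] = []
    for r in fam.rows:
        if r.species_id not in groups:
            groups[r.species_id] = []
            order.append(r.species_id)
        groups[r.species_id].append(r)

    if keep == "first":
        chooser: Callable[[list[FamilyRow]], FamilyRow] = lambda rows: rows[0]
    elif callable(keep):
        chooser = keep
    else:
        raise ValueError(f"unknown keep rule {keep!r}")

    kept = [chooser(groups[sp]) for sp in order]
    # preserve the reference row if duplicates would drop it
    ref = fam.reference_seq_id
    if ref is not None and all(r.seq_id != ref for r in kept):
        ref_row = fam.row_by_seq_id(ref)
        kept = [ref_row if r.species_id == ref_row.species_id else r for r in kept]
    n_dropped = fam.n_rows - len(kept)
    if n_dropped:
        logger.info(
            "family %s: dropped %d redundant within-species sequences",
            fam.name,
            n_dropped,
        )
    return replace(fam, rows=kept)


@dataclass
class ColumnMap:
    """Aligned-column to ungapped-reference-residue mapping (both 1-based).

    Columns where the reference sequence carries a gap have no image; for
    all other columns ``aligned_to_ref[col]`` is the residue number in the
    original, unaligned reference protein.
    """

    family_name: str
    reference_seq_id: str
    aligned_to_ref: dict[int, int]

    @property
    def reference_length(self) -> int:
        """Gapless length of the reference sequence."""
        return max(self.aligned_to_ref.values(), default=0)

    def ref_index(self, aligned_col: int) -> int | None:
        """Residue number for an aligned column, or ``None`` at a ref gap."""
        return self.aligned_to_ref.get(aligned_col)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("aligned_col\tref_residue\n")
            for col in sorted(self.aligned_to_ref):
                fh.write(f"{col}\t{self.aligned_to_ref[col]}\n")


def build_column_map(fam: AlignedFamily, reference_seq_id: str | None = None) -> ColumnMap:
    """Map aligned columns to the reference sequence's residue numbers.

    Every column where the reference is not gapped maps to its 1-based
    position in the ungapped reference; the map is strictly increasing in
    both coordinates by construction.
    """
    ref_id = reference_seq_id if reference_seq_id is not None else fam.reference_seq_id
    if ref_id is None:
        raise ValueError(f"family {fam.name!r}: no reference sequence id given")
    ref_row = fam.row_by_seq_id(ref_id)
    mapping: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(ref_row.residues, start=1):
        if ch != GAP:
            res += 1
            mapping[col] = res
    return ColumnMap(family_name=fam.name, reference_seq_id=ref_id, aligned_to_ref=mapping)
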