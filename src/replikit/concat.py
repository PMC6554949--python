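"""Species-matched concatenation of two aligned families.

To score coevolution *between* two proteins, each species' orthologues from
the two families are joined into one long row.  A constant poly-asparagine
buffer (default 20 residues) separates the two segments; it makes the
segment boundary unambiguous in downstream output and, being invariant,
carries no covariance signal of its own.  Pairs involving linker columns are
always excluded from reported scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from replikit.msa import AlignedFamily, ColumnMap, build_column_map

logger = logging.getLogger(__name__)

DEFAULT_LINKER_LENGTH = 20
DEFAULT_LINKER_CHAR = "N"

SEGMENT_A = "A"
SEGMENT_B = "B"
SEGMENT_LINKER = "linker"


class PairingError(ValueError):
    """The two families share no species, or cannot be paired."""


@dataclass
class PairedAlignment:
    """Concatenated alignment ``[family A | linker | family B]``.

    ``rows`` holds ``(species_id, residues)`` with every residue string of
    length ``L_A + linker_length + L_B``.  Column ranges (1-based):
    A = ``1..L_A``, linker = ``L_A+1..L_A+linker_length``, B = the rest.
    """

    rows: list[tuple[str, str]]
    L_A: int
    L_B: int
    linker_length: int = DEFAULT_LINKER_LENGTH
    linker_char: str = DEFAULT_LINKER_CHAR
    family_a_name: str = "familyA"
    family_b_name: str = "familyB"
    column_map_a: ColumnMap | None = None
    column_map_b: ColumnMap | None = None
    reference_species: str | None = None

    @property
    def total_length(self) -> int:
        return self.L_A + self.linker_length + self.L_B

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def species_ids(self) -> list[str]:
        return [sp for sp, _ in self.rows]

    def segment_of(self, col: int) -> str:
        """Segment label for a 1-based concatenated column."""
        if not 1 <= col <= self.total_length:
            raise IndexError(
                f"column {col} out of range 1..{self.total_length}"
            )
        if col <= self.L_A:
            return SEGMENT_A
        if col <= self.L_A + self.linker_length:
            return SEGMENT_LINKER
        return SEGMENT_B

    def split_row(self, residues: str) -> tuple[str, str]:
        """Recover the family-A and family-B parts of a concatenated row."""
        return residues[: self.L_A], residues[self.L_A + self.linker_length :]

    def b_offset(self) -> int:
        """Number of columns preceding segment B."""
        return self.L_A + self.linker_length


def concatenate_families(
    fam_a: AlignedFamily,
    fam_b: AlignedFamily,
    linker_length: int = DEFAULT_LINKER_LENGTH,
    linker_char: str = DEFAULT_LINKER_CHAR,
) -> PairedAlignment:
    """Join two one-per-species families into a :class:`PairedAlignment`.

    Only species present in both families are kept (ordered by their
    appearance in ``fam_a``); species found in a single family are dropped
    with a logged count.  If both families designate reference sequences
    they must come from the same species, and the per-family column maps are
    attached for later renumbering.
    """
    for fam in (fam_a, fam_b):
        ids = fam.species_ids
        if len(ids) != len(set(ids)):
            raise PairingError(
                f"family {fam.name!r} is not one-per-species; "
                "apply one_per_species_filter first"
            )
    species_b = set(fam_b.species_ids)
    shared = [sp for sp in fam_a.species_ids if sp in species_b]
    if not shared:
        raise PairingError(
            f"families {fam_a.name!r} and {fam_b.name!r} share no species"
        )
    n_dropped = (fam_a.n_rows - len(shared)) + (fam_b.n_rows - len(shared))
    if n_dropped:
        logger.info("dropped %d species present in only one family", n_dropped)

    cmap_a = cmap_b = None
    ref_species = None
    if fam_a.reference_seq_id is not None and fam_b.reference_seq_id is not None:
        ref_sp_a = fam_a.reference_row.species_id
        ref_sp_b = fam_b.reference_row.species_id
        if ref_sp_a != ref_sp_b:
            raise PairingError(
                f"reference sequences come from different species: "
                f"{ref_sp_a!r} vs {ref_sp_b!r}"
            )
        if ref_sp_a not in species_b or ref_sp_a not in set(fam_a.species_ids):
            raise PairingError("reference species is not shared by both families")
        cmap_a = build_column_map(fam_a)
        cmap_b = build_column_map(fam_b)
        ref_species = ref_sp_a

    linker = linker_char * linker_length
    rows = [
        (sp, fam_a.row_by_species(sp).residues + linker + fam_b.row_by_species(sp).residues)
        for sp in shared
    ]
    return PairedAlignment(
        rows=rows,
        L_A=fam_a.aligned_length,
        L_B=fam_b.aligned_length,
        linker_length=linker_length,
        linker_char=linker_char,
        family_a_name=fam_a.name,
        family_b_name=fam_b.name,
        column_map_a=cmap_a,
        column_map_b=cmap_b,
        reference_species=ref_species,
    )


PAIR_AA = "AA"
PAIR_AB = "AB"
PAIR_BB = "BB"
PAIR_LINKER = "involves-linker"


def classify_pair(i: int, j: int, pa: PairedAlignment) -> str:
    """Label the segment pair of concatenated columns ``(i, j)``.

    Returns ``"AA"``, ``"AB"``, ``"BB"`` or ``"involves-linker"``; the
    coevolution analysis keeps only inter-protein (``"AB"``) pairs.
    """
    seg_i = pa.segment_of(i)
    seg_j = pa.segment_of(j)
    if SEGMENT_LINKER in (seg_i, seg_j):
        return PAIR_LINKER
    return "".join(sorted(seg_i + seg_j))


def write_paired_fasta(pa: PairedAlignment, fasta_path: str | Path,
                       sidecar_path: str | Path | None = None) -> None:
    """Write the combined alignment plus a JSON sidecar of segment bounds."""
    records = [
        SeqRecord(Seq(seq), id=sp, description="") for sp, seq in pa.rows
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    if sidecar_path is None:
        sidecar_path = Path(fasta_path).with_suffix(".segments.json")
    sidecar = {
        "family_a": pa.family_a_name,
        "family_b": pa.family_b_name,
        "L_A": pa.L_A,
        "linker_length": pa.linker_length,
        "linker_char": pa.linker_char,
        "L_B": pa.L_B,
        "segments": {
            "A": [1, pa.L_A],
            "linker": [pa.L_A + 1, pa.L_A + pa.linker_length],
            "B": [pa.b_offset() + 1, pa.total_length],
        },
        "n_species": pa.n_rows,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
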