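"""Region-restricted percent sequence identity from pairwise alignments.

Template choice for receptor modelling is usually summarized by the percent
identity between target and template over the transmembrane helices (TM)
and the binding-site residues (BS), not over the whole sequence.  Identity
here is computed per *target* region position: the denominator is the
number of region residues of the target, and a region residue aligned
opposite a template gap counts as a mismatch.  Comparison is
case-insensitive; the ambiguity code 'X' never matches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentFormatError",
    "InvalidRegionError",
    "PairwiseAlignment",
    "read_alignment",
    "write_alignment",
    "region_identity",
]

_GAP_CHARS = {"-", ".", "~"}


class AlignmentFormatError(ValueError):
    """Alignment text is not a two-sequence alignment."""


class InvalidRegionError(ValueError):
    """Region is empty or references positions absent from the target."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows plus a per-column target numbering.

    ``column_map[c]`` is the target residue number occupying column ``c``,
    or None for target-gap columns.  Target numbering starts at
    ``target_start`` (author numbering offset).
    """

    target_name: str
    template_name: str
    target_row: str
    template_row: str
    target_start: int = 1

    def __post_init__(self) -> None:
        if len(self.target_row) != len(self.template_row):
            raise AlignmentFormatError("aligned rows differ in length")
        norm = lambda row: "".join(
            "-" if ch in _GAP_CHARS else ch.upper() for ch in row
        )
        object.__setattr__(self, "target_row", norm(self.target_row))
        object.__setattr__(self, "template_row", norm(self.template_row))

    @property
    def column_map(self) -> list[int | None]:
        out: list[int | None] = []
        number = self.target_start
        for ch in self.target_row:
            if ch == "-":
                out.append(None)
            else:
                out.append(number)
                number += 1
        return out

    @property
    def target_sequence(self) -> str:
        return self.target_row.replace("-", "")


def read_alignment(
    text: str, fmt: str = "fasta", target_start: int = 1
) -> PairwiseAlignment:
    """Parse a two-sequence FASTA or Clustal alignment."""
    if fmt not in {"fasta", "clustal"}:
        raise AlignmentFormatError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(io.StringIO(text), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot parse alignment: {exc}") from exc
    if len(aln) != 2:
        raise AlignmentFormatError(
            f"pairwise alignment must contain exactly 2 sequences, got {len(aln)}"
        )
    return PairwiseAlignment(
        target_name=aln[0].id,
        template_name=aln[1].id,
        target_row=str(aln[0].seq),
        template_row=str(aln[1].seq),
        target_start=target_start,
    )


def write_alignment(aln: PairwiseAlignment, fmt: str = "fasta") -> str:
    msa = MultipleSeqAlignment(
        [
            SeqRecord(Seq(aln.target_row), id=aln.target_name, description=""),
            SeqRecord(Seq(aln.template_row), id=aln.template_name, description=""),
        ]
    )
    buf = io.StringIO()
    AlignIO.write(msa, buf, fmt)
    return buf.getvalue()


def region_identity(aln: PairwiseAlignment, positions: set[int]) -> float:
    """Percent identity over the given target residue numbers.

    Denominator is the region size; a region position aligned to a template
    gap (or to 'X') counts as a mismatch.
    """
    if not positions:
        raise InvalidRegionError("region is empty")
    pos_to_col = {
        p: c for c, p in enumerate(aln.column_map) if p is not None
    }
    missing = sorted(p for p in positions if p not in pos_to_col)
    if missing:
        raise InvalidRegionError(
            f"region positions absent from target: {missing[:10]}"
        )
    matches = 0
    for p in positions:
        col = pos_to_col[p]
        t, q = aln.target_row[col], aln.template_row[col]
        if t == q and t not in {"-", "X"}:
            matches += 1
    return 100.0 * matches / len(positions)
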