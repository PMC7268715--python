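"""Sequence and primer I/O with IUPAC-aware primitives.

All sequences are normalized on load: upper-case, RNA ``U`` mapped to ``T``,
and alignment gap characters (``-``, ``.``) stripped — reference 16S
collections are often distributed as RNA-alphabet or pre-aligned FASTA, while
every downstream operation works on unaligned DNA.  The IUPAC degeneracy
codes (R = G/A, Y = T/C, K = G/T, M = A/C, S = G/C, W = A/T, B/D/H/V =
three-base codes, N = any) are first-class citizens here: primers carry them,
and matching is defined as non-empty intersection of the concrete-base sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "IUPAC_SETS",
    "NucSequence",
    "Primer",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_primer_config",
    "reverse_complement",
    "iupac_match",
    "normalize_residues",
]

#: concrete-base expansion of every IUPAC nucleotide code (DNA alphabet)
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")
_GAP_CHARS = {"-", "."}


class FastaParseError(ValueError):
    """Raised when a FASTA record fails validation; names the offending record."""


def normalize_residues(residues: str, *, record_id: str = "<sequence>") -> str:
    """Upper-case, map U->T, strip gap characters, and validate the alphabet.

    Raises :class:`FastaParseError` naming ``record_id`` on an illegal
    character or an empty (post-stripping) sequence.
    """
    s = residues.upper().replace("U", "T")
    if any(c in _GAP_CHARS for c in s):
        warnings.warn(
            f"record {record_id!r}: gap characters stripped "
            "(alignment-format input treated as unaligned sequence)",
            stacklevel=2,
        )
        s = s.replace("-", "").replace(".", "")
    if not s:
        raise FastaParseError(f"record {record_id!r}: empty sequence")
    bad = set(s) - set(IUPAC_SETS)
    if bad:
        raise FastaParseError(
            f"record {record_id!r}: illegal character(s) {sorted(bad)} "
            "outside the IUPAC nucleotide alphabet"
        )
    return s


@dataclass(frozen=True)
class NucSequence:
    """A named nucleotide sequence over the IUPAC alphabet (normalized DNA)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, record_id=self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Primer:
    """A PCR primer written 5'->3' with IUPAC degeneracy.

    ``orientation`` is ``"forward"`` (anneals to the minus strand, extends
    along the plus strand) or ``"reverse"`` (anneals to the plus strand).
    """

    name: str
    residues: str
    orientation: str = field(default="forward")

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, record_id=self.name)
        )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(
                f"primer {self.name!r}: orientation must be 'forward' or "
                f"'reverse', got {self.orientation!r}"
            )
        if len(self.residues) < 10:
            raise ValueError(
                f"primer {self.name!r}: length {len(self.residues)} < 10"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: Union[str, Path]) -> list[NucSequence]:
    """Read a (multi-record) FASTA file into normalized :class:`NucSequence`.

    The record id is the first whitespace-delimited token of the header; the
    remainder of the header is kept as ``description``.  Record order is
    preserved.  An empty file yields an empty list.
    """
    path = Path(path)
    records: list[NucSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        try:
            records.append(NucSequence(id=rec.id, residues=str(rec.seq), description=desc))
        except FastaParseError as exc:
            raise FastaParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[NucSequence], path: Union[str, Path], width: int = 70) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta` for normalized input."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_primer_config(path: Union[str, Path]) -> dict[str, Primer]:
    """Read primers from a TOML config file.

    Expected layout::

        [primers.799F]
        sequence = "AACMGGATTAGATACCCKG"
        orientation = "forward"

    A top-level ``[primers]`` table is optional; bare ``[NAME]`` tables with a
    ``sequence`` key work too.  Returns a name -> :class:`Primer` mapping.
    """
    import tomllib

    path = Path(path)
    with path.open("rb") as fh:
        doc = tomllib.load(fh)
    table = doc.get("primers", doc)
    primers: dict[str, Primer] = {}
    for name, entry in table.items():
        if not isinstance(entry, dict) or "sequence" not in entry:
            raise ValueError(f"{path}: primer {name!r} needs a 'sequence' key")
        orientation = entry.get("orientation")
        if orientation is None:
            # conventional suffix: ...F forward, ...R reverse
            orientation = "reverse" if name.upper().endswith("R") else "forward"
        primers[name] = Primer(name=name, residues=entry["sequence"], orientation=orientation)
    return primers


def reverse_complement(s: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes map correctly)."""
    su = s.upper()
    bad = set(su) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"illegal character(s) {sorted(bad)} in {s!r}")
    return su.translate(_COMPLEMENT)[::-1]


def iupac_match(template_base: str, primer_base: str) -> bool:
    """True iff the concrete-base sets of the two IUPAC codes intersect.

    Exact bases match themselves; ``N`` matches everything; e.g.
    ``iupac_match("A", "R")`` is true because R covers G and A.
    """
    try:
        a = IUPAC_SETS[template_base.upper()]
        b = IUPAC_SETS[primer_base.upper()]
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC character {exc.args[0]!r}") from None
    return bool(a & b)


# sanity: Biopython's complement agrees with ours on the full alphabet
assert str(Seq("ACGTRYKMSWBDHVN").reverse_complement()) == reverse_complement("ACGTRYKMSWBDHVN")
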