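"""Enumeration of Cas9-targetable guide sites on host 16S rRNA genes.

A guide site is a 20-nt protospacer immediately 5' of a PAM (5'-NGG-3' for
SpCas9).  Both strands of the host gene are scanned because the amplicon to
be cleaved is double-stranded: a guide on either strand directs cleavage.
Protospacers are reported 5'->3' with the PAM-proximal base last, which is
the orientation in which the off-target aligner consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import NucSequence, iupac_match, reverse_complement

__all__ = ["GuideSite", "enumerate_guides"]

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class GuideSite:
    """A candidate Cas9 target on a host gene.

    ``start``/``end`` are 0-based half-open coordinates of the protospacer on
    the plus strand of the source sequence regardless of ``strand``; for a
    minus-strand site the protospacer is the reverse complement of that slice
    and the PAM lies immediately 5' of ``start`` on the plus strand.
    """

    guide_id: str
    source_id: str
    strand: str  # "+" or "-"
    start: int
    end: int
    protospacer: str
    pam: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.protospacer):
            raise ValueError("coordinates inconsistent with protospacer length")


def _pam_matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        iupac_match(t, p) for t, p in zip(window, pattern)
    )


def enumerate_guides(
    seq: NucSequence,
    guide_len: int = 20,
    pam_pattern: str = "NGG",
    both_strands: bool = True,
    id_prefix: str = "gRNA",
) -> list[GuideSite]:
    """Return every guide site on ``seq`` (both strands by default).

    A site is a ``guide_len`` window of unambiguous ACGT immediately followed
    3' by a window matching ``pam_pattern`` (IUPAC-aware; the PAM window must
    itself be unambiguous in the template).  Windows containing degenerate
    bases are skipped, not expanded — a guide must be a synthesizable,
    unambiguous oligo.  All overlapping sites are reported.

    Guide ids are ``"<id_prefix><p>"`` where ``p`` is the 1-based plus-strand
    coordinate of the protospacer base closest to the PAM (its 3' end on the
    plus strand for ``+`` sites, its 5'-most plus-strand base for ``-``
    sites).  Results are sorted by (strand, start).

    Sequences shorter than ``guide_len + len(pam_pattern)`` yield ``[]``.
    """
    if guide_len < 1:
        raise ValueError("guide_len must be >= 1")
    pam_len = len(pam_pattern)
    sites: list[GuideSite] = []

    def scan(residues: str, strand: str, seqlen: int) -> None:
        for i in range(0, len(residues) - guide_len - pam_len + 1):
            proto = residues[i : i + guide_len]
            pam = residues[i + guide_len : i + guide_len + pam_len]
            if not _UNAMBIGUOUS.issuperset(proto) or not _UNAMBIGUOUS.issuperset(pam):
                continue
            if not _pam_matches(pam, pam_pattern):
                continue
            if strand == "+":
                start, end = i, i + guide_len
                pam_proximal = end  # 1-based coordinate of the base next to the PAM
            else:
                # coordinates mirrored back onto the plus strand
                start = seqlen - (i + guide_len)
                end = seqlen - i
                pam_proximal = start + 1
            sites.append(
                GuideSite(
                    guide_id=f"{id_prefix}{pam_proximal}",
                    source_id=seq.id,
                    strand=strand,
                    start=start,
                    end=end,
                    protospacer=proto,
                    pam=pam,
                )
            )

    n = len(seq.residues)
    scan(seq.residues, "+", n)
    if both_strands:
        scan(reverse_complement(seq.residues), "-", n)
    sites.sort(key=lambda s: (s.strand, s.start))
    # positional names can collide across strands; disambiguate deterministically
    seen: dict[str, int] = {}
    unique: list[GuideSite] = []
    for s in sites:
        k = seen.get(s.guide_id, 0) + 1
        seen[s.guide_id] = k
        if k > 1:
            s = GuideSite(
                guide_id=f"{s.guide_id}.{k}",
                source_id=s.source_id,
                strand=s.strand,
                start=s.start,
                end=s.end,
                protospacer=s.protospacer,
                pam=s.pam,
            )
        unique.append(s)
    return unique
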