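"""In-silico PCR with degenerate universal primers.

Universal 16S primers anneal in conserved regions and are written with IUPAC
degeneracy codes; a primer matches a template window when every position's
concrete-base sets intersect (mismatches may be tolerated, indels are not —
primer-template bulges do not amplify in practice).  Amplicon products are
primer-inclusive: the reported coordinates and sequence span from the first
base of the forward primer footprint to the last base of the reverse primer
footprint, which is how product lengths are compared on a gel.

Intersecting guide sites with amplicons answers the design question of which
guides can cleave a given primer pair's product: a guide is usable only if
its protospacer and PAM lie entirely inside the amplified region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .guides import GuideSite
from .seqio import NucSequence, Primer, iupac_match, reverse_complement

__all__ = ["PrimerSite", "Amplicon", "find_primer_sites", "simulate_amplicon", "guides_in_amplicon"]


@dataclass(frozen=True)
class PrimerSite:
    template_id: str
    primer_name: str
    strand: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    fwd_site: PrimerSite
    rev_site: PrimerSite
    start: int
    end: int
    sequence: str
    nested: bool = False  # overlaps or contains another reported product

    @property
    def length(self) -> int:
        return self.end - self.start


def _count_mismatches(window: str, probe: str, limit: int) -> int:
    """Mismatches between template window and probe under IUPAC matching; -1 if > limit."""
    mm = 0
    for t, p in zip(window, probe):
        if not iupac_match(t, p):
            mm += 1
            if mm > limit:
                return -1
    return mm


def find_primer_sites(
    template: NucSequence, primer: Primer, max_mismatch: int = 0
) -> list[PrimerSite]:
    """All annealing sites of ``primer`` on ``template`` with <= ``max_mismatch``.

    Forward primers are scanned against the plus strand; reverse primers are
    scanned as their reverse complement against the plus strand (equivalent
    to matching the primer on the minus strand).  No indels.
    """
    if primer.orientation == "forward":
        probe, strand = primer.residues, "+"
    else:
        probe, strand = reverse_complement(primer.residues), "-"
    plen = len(probe)
    seq = template.residues
    sites = []
    for i in range(0, len(seq) - plen + 1):
        mm = _count_mismatches(seq[i : i + plen], probe, max_mismatch)
        if mm >= 0:
            sites.append(
                PrimerSite(
                    template_id=template.id,
                    primer_name=primer.name,
                    strand=strand,
                    start=i,
                    end=i + plen,
                    mismatches=mm,
                )
            )
    return sites


def simulate_amplicon(
    template: NucSequence,
    fwd: Primer,
    rev: Primer,
    max_product_len: int = 5000,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Products of a primer pair on one template.

    One amplicon per (forward site, reverse site) pair with the forward site
    upstream and a primer-inclusive product no longer than
    ``max_product_len``.  All products are reported; products that overlap
    another are flagged ``nested`` rather than silently dropped.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError(
            f"primer orientations mixed up: {fwd.name} is {fwd.orientation}, "
            f"{rev.name} is {rev.orientation}"
        )
    fwd_sites = find_primer_sites(template, fwd, max_mismatch)
    rev_sites = find_primer_sites(template, rev, max_mismatch)
    products = []
    for fs in fwd_sites:
        for rs in rev_sites:
            if rs.start >= fs.end and rs.end - fs.start <= max_product_len:
                products.append(
                    Amplicon(
                        template_id=template.id,
                        fwd_site=fs,
                        rev_site=rs,
                        start=fs.start,
                        end=rs.end,
                        sequence=template.residues[fs.start : rs.end],
                    )
                )
    if len(products) > 1:
        flagged = []
        for k, a in enumerate(products):
            overlap = any(
                b.start < a.end and a.start < b.end
                for j, b in enumerate(products)
                if j != k
            )
            flagged.append(
                Amplicon(
                    template_id=a.template_id,
                    fwd_site=a.fwd_site,
                    rev_site=a.rev_site,
                    start=a.start,
                    end=a.end,
                    sequence=a.sequence,
                    nested=overlap,
                )
            )
        products = flagged
    products.sort(key=lambda a: (a.start, a.end))
    return products


def guides_in_amplicon(guides: Sequence[GuideSite], amplicon: Amplicon) -> list[GuideSite]:
    """Guides whose protospacer AND PAM lie fully inside the product.

    Guides and amplicon must share template coordinates.  For a plus-strand
    guide the PAM occupies the 3 nt 3' of the protospacer on the plus
    strand; for a minus-strand guide it occupies the 3 nt 5' of ``start``.
    Either strand qualifies — the product is double-stranded.
    """
    hits = []
    for g in guides:
        if g.source_id != amplicon.template_id:
            continue
        if g.strand == "+":
            lo, hi = g.start, g.end + 3
        else:
            lo, hi = g.start - 3, g.end
        if lo >= amplicon.start and hi <= amplicon.end:
            hits.append(g)
    return hits
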