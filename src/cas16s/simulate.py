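"""Synthetic references, mock communities, and the Cas9 digestion model.

Two jobs live here.  First, a seeded generator of synthetic 16S-like
reference sets with *planted* near-matches of a guide — each plant applies a
chosen number of edits at chosen guide positions and appends a PAM of a
chosen class, so the off-target scanner can be exercised against sites whose
correct classification is known by construction.  Second, an expected-value
model of Cas9 digestion of an amplicon community: cleaved molecules do not
re-amplify in the index PCR, so each member's fraction is reweighted by its
survival probability

    f_i' = f_i (1 - e_i) / sum_j f_j (1 - e_j)

where e_i is the member's cleavage efficiency.  The model is deterministic
at the fraction level; stochasticity enters only through multinomial read
sampling (:func:`sample_counts`), which emulates a rarefied OTU table.  For
a two-member community with host fraction h this reduces to the closed form
h' = h(1-e)/(1-he).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import NucSequence

__all__ = [
    "CommunityMember",
    "CommunityProfile",
    "DigestModel",
    "PlantSpec",
    "PlantedSite",
    "generate_reference_db",
    "synthetic_16s_gene",
    "digest_community",
    "sample_counts",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunityMember:
    member_id: str
    fraction: float
    is_host: bool = False


@dataclass(frozen=True)
class CommunityProfile:
    """Relative composition of an amplicon pool; fractions sum to 1."""

    members: tuple[CommunityMember, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("profile needs at least one member")
        if any(m.fraction < 0 for m in self.members):
            raise ValueError("fractions must be non-negative")
        total = sum(m.fraction for m in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total!r}, expected 1")

    @classmethod
    def from_pairs(cls, pairs, host_ids=()) -> "CommunityProfile":
        return cls(
            tuple(
                CommunityMember(mid, frac, mid in set(host_ids)) for mid, frac in pairs
            )
        )

    def fraction_of(self, member_id: str) -> float:
        for m in self.members:
            if m.member_id == member_id:
                return m.fraction
        raise KeyError(member_id)

    @property
    def host_fraction(self) -> float:
        return sum(m.fraction for m in self.members if m.is_host)


@dataclass(frozen=True)
class DigestModel:
    """Per-member cleavage efficiencies e in [0, 1]; absent members are uncut."""

    cleavage_efficiency: dict

    def __post_init__(self) -> None:
        for mid, e in self.cleavage_efficiency.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficiency for {mid!r} is {e}, outside [0, 1]")

    def efficiency(self, member_id: str) -> float:
        return self.cleavage_efficiency.get(member_id, 0.0)


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one planted candidate site derived from a guide.

    ``edit_positions`` are guide positions counted from the PAM (1 =
    PAM-adjacent); each listed position receives a substitution.  An edit at
    position 1 breaks the anchored-match requirement, so requesting it with
    ``expected_call=True`` is a contradiction and rejected.
    """

    guide: str
    n_edits: int
    edit_positions: frozenset = field(default_factory=frozenset)
    pam_class: str = "NGG"
    expected_call: bool = True

    def __post_init__(self) -> None:
        if len(self.guide) != 20 or not set(self.guide) <= set("ACGT"):
            raise ValueError("guide must be a 20-nt ACGT string")
        positions = frozenset(self.edit_positions)
        object.__setattr__(self, "edit_positions", positions)
        if len(positions) != self.n_edits:
            raise ValueError("edit_positions size must equal n_edits")
        if positions and not all(1 <= p <= 20 for p in positions):
            raise ValueError("edit positions must lie in 1..20")
        if self.pam_class not in ("NGG", "NAG"):
            raise ValueError("pam_class must be NGG or NAG")
        if 1 in positions and self.expected_call:
            raise ValueError(
                "an edit at position 1 (PAM-adjacent) can never yield an "
                "off-target under the anchored rule; expected_call=True is "
                "contradictory"
            )


@dataclass(frozen=True)
class PlantedSite:
    """Where a PlantSpec landed: sequence index, plus-strand site coordinates."""

    spec: PlantSpec
    seq_index: int
    start: int  # protospacer start, 0-based on the plus strand
    site: str  # the embedded 20-mer (PAM-proximal last)
    pam: str


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


# deterministic transversion used for planted substitutions: the planted
# site is then a pure function of (guide, edit_positions), so its expected
# classification can be derived once and holds for every seed
_TRANSVERSION = str.maketrans("ACGT", "CATG")


def _apply_edits(guide: str, spec: PlantSpec) -> str:
    site = list(guide)
    for p in sorted(spec.edit_positions):
        i = 20 - p  # position 1 from the PAM = last character
        site[i] = site[i].translate(_TRANSVERSION)
    return "".join(site)


def generate_reference_db(
    n_seqs: int,
    seq_len: int,
    plants: Sequence[PlantSpec] = (),
    seed: int = 0,
) -> tuple[list[NucSequence], list[PlantedSite]]:
    """Seeded synthetic reference set with planted candidate sites.

    Returns ``n_seqs`` pseudorandom ACGT sequences of ``seq_len``; plant k is
    embedded on the plus strand of sequence ``k mod n_seqs`` at a random
    offset, as the edited 20-mer followed by a PAM of the requested class
    (N drawn at random, then GG or AG).  Fully reproducible from ``seed``.
    """
    if seq_len < 23:
        raise ValueError("seq_len must be >= 23 to hold a site and PAM")
    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    rng = np.random.default_rng(seed)
    seqs = [_random_seq(rng, seq_len) for _ in range(n_seqs)]
    planted: list[PlantedSite] = []
    for k, spec in enumerate(plants):
        idx = k % n_seqs
        site = _apply_edits(spec.guide, spec)
        pam = _BASES[int(rng.integers(4))] + ("GG" if spec.pam_class == "NGG" else "AG")
        start = int(rng.integers(0, seq_len - 23 + 1))
        s = seqs[idx]
        seqs[idx] = s[:start] + site + pam + s[start + 23 :]
        planted.append(PlantedSite(spec=spec, seq_index=idx, start=start, site=site, pam=pam))
    records = [
        NucSequence(id=f"synth_{i}", residues=s, description=f"synthetic reference seed={seed}")
        for i, s in enumerate(seqs)
    ]
    return records, planted


def synthetic_16s_gene(
    seed: int, length: int = 1500, seq_id: str = "synthetic_host_16S"
) -> NucSequence:
    """A synthetic stand-in for a host organelle 16S rRNA gene.

    A uniform pseudorandom ACGT sequence of the typical 16S gene length —
    synthetic, not derived from any real organelle sequence; useful for
    exercising the guide-design workflow end to end without reference data.
    """
    rng = np.random.default_rng(seed)
    return NucSequence(
        id=seq_id,
        residues=_random_seq(rng, length),
        description=f"synthetic pseudorandom gene seed={seed}",
    )


def digest_community(profile: CommunityProfile, model: DigestModel) -> CommunityProfile:
    """Post-digestion composition under the expected-value survival model.

    Raises if every molecule is cleaved (no template survives for the index
    PCR — complete depletion).
    """
    survival = [m.fraction * (1.0 - model.efficiency(m.member_id)) for m in profile.members]
    denom = sum(survival)
    if denom <= 0.0:
        raise ValueError("complete depletion: no amplifiable template survives digestion")
    return CommunityProfile(
        tuple(
            CommunityMember(m.member_id, s / denom, m.is_host)
            for m, s in zip(profile.members, survival)
        )
    )


def sample_counts(profile: CommunityProfile, depth: int, seed: int = 0) -> dict:
    """Multinomial read sampling at ``depth``; emulates a rarefied OTU table."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    fractions = np.array([m.fraction for m in profile.members], dtype=float)
    fractions = fractions / fractions.sum()
    draws = rng.multinomial(depth, fractions)
    return {m.member_id: int(c) for m, c in zip(profile.members, draws)}
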