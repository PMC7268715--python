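"""Shared fixtures: seeded random sequences and a slow, independent scanner.

The brute-force helpers here deliberately avoid the package's own scanning
and alignment code paths so they can serve as oracles.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from cas16s.seqio import NucSequence

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def simple_revcomp(s: str) -> str:
    """Independent ACGT reverse complement (oracle helper)."""
    return "".join(_COMP[c] for c in reversed(s))


def brute_force_pam_windows(seq: str, pam_dinucs=("GG",), guide_len: int = 20):
    """Every (strand, protospacer, pam) by naive scanning of both strands."""
    out = []
    for strand, s in (("+", seq), ("-", simple_revcomp(seq))):
        for i in range(len(s) - guide_len - 3 + 1):
            proto = s[i : i + guide_len]
            pam = s[i + guide_len : i + guide_len + 3]
            if set(proto + pam) <= set("ACGT") and pam[1:] in pam_dinucs:
                out.append((strand, proto, pam))
    return out


@pytest.fixture
def random_dna():
    def make(length: int, seed: int) -> str:
        rng = random.Random(seed)
        return "".join(rng.choice("ACGT") for _ in range(length))

    return make


@pytest.fixture
def random_refs(random_dna):
    def make(n: int, length: int, seed: int) -> list[NucSequence]:
        return [
            NucSequence(id=f"ref_{i}", residues=random_dna(length, seed * 10_000 + i))
            for i in range(n)
        ]

    return make
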