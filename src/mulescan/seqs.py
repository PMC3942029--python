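"""Small nucleotide/protein sequence helpers shared across modules."""

from __future__ import annotations

import re

import numpy as np

COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: IUPAC nucleotide ambiguity codes
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif into a regular expression."""
    parts = []
    for c in motif.upper():
        bases = IUPAC.get(c)
        if bases is None:
            raise ValueError(f"not an IUPAC nucleotide code: {c!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def matches_iupac(seq: str, motif: str) -> bool:
    """True when *seq* matches *motif* exactly (same length)."""
    return len(seq) == len(motif) and iupac_regex(motif).fullmatch(seq.upper()) is not None


def random_nt(rng: np.random.Generator, length: int, gc: float = 0.40) -> str:
    """An i.i.d. random nucleotide string with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(codes, size=length, p=p).tobytes().decode()


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
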