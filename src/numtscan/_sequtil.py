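"""Small shared helpers for nucleotide strings."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

_IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_nucleotides(seq: str, name: str = "sequence") -> None:
    """Reject empty sequences or sequences with non-IUPAC characters."""
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq.upper()) - IUPAC_CODES
    if bad:
        raise ValueError(
            f"{name} contains non-IUPAC characters: {sorted(bad)!r}"
        )


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """Uniform random A/C/G/T string."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def iupac_regex(motif: str) -> str:
    """Translate an IUPAC motif (e.g. ATCGAT, GANTC) into a regex."""
    parts = []
    for ch in motif.upper():
        try:
            exp = _IUPAC_EXPAND[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code in motif: {ch!r}") from None
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return "".join(parts)


def encode_bases(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3; any other character to 255."""
    table = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    for i, b in enumerate(b"acgt"):
        table[b] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
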