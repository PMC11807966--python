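"""Shared amplicon layout constants and small DNA utilities.

The amplicon analysed by this package is the N-terminal repetitive domain
of an alpha-gliadin transcript.  On the forward strand a merged amplicon
reads:

    [8 nt line barcode][forward primer][signal-peptide remainder]
    [coding core (the epitope-bearing region)][revcomp(reverse primer)]

The degenerate forward primer encodes the start of the signal peptide
(MKTF[LP]I); the reverse primer binds inside the PISQQQ motif, so its
reverse complement terminates the amplicon.  The simulator and the
preprocessing stage share these constants so that a simulated read can be
stripped back to exactly the core it was built from.
"""

from __future__ import annotations

import numpy as np

# Degenerate gene-specific primers (IUPAC codes lowercase in the lab sheet,
# uppercase here).  Forward: atgaaracmtttcycatc; reverse: ctgctgctgtgaaattrgwt.
FORWARD_PRIMER = "ATGAARACMTTTCYCATC"
REVERSE_PRIMER = "CTGCTGCTGTGAAATTRGWT"

BARCODE_LENGTH = 8

# Signal-peptide residues downstream of the primer-encoded MKTF[LP]I.
# Fixed by construction in the simulator; the strip stage removes the same
# number of nucleotides (positional removal, offset configurable for real
# data where the layout may differ).
SIGNAL_REST_AA = "LALLAIVATTATTA"
SIGNAL_REST_NT_LENGTH = 3 * len(SIGNAL_REST_AA)  # 42

CORE_OFFSET = BARCODE_LENGTH + len(FORWARD_PRIMER) + SIGNAL_REST_NT_LENGTH
REV_TAIL_LENGTH = len(REVERSE_PRIMER)

# Observed coding-region length window (nt) used as the default length filter.
DEFAULT_LENGTH_BOUNDS = (192, 432)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT",
    "S": "CG", "W": "AT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYMKSWBDHVN",
    "TGCAYRKMSWVHDBN",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern_char: str, base: str) -> bool:
    """True if ``base`` is compatible with the IUPAC ``pattern_char``."""
    return base in IUPAC[pattern_char]


def iupac_mismatches(pattern: str, seq: str, cap: int | None = None) -> int:
    """Mismatches of ``seq`` against an IUPAC ``pattern`` of equal length.

    Counting stops early once ``cap`` + 1 mismatches are seen (the exact
    count above the cap is irrelevant to callers).
    """
    if len(pattern) != len(seq):
        raise ValueError("pattern and sequence lengths differ")
    mm = 0
    for p, b in zip(pattern, seq):
        if b not in IUPAC[p]:
            mm += 1
            if cap is not None and mm > cap:
                return mm
    return mm


def hamming(a: str, b: str, cap: int | None = None) -> int:
    """Hamming distance between equal-length strings, with optional cap."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if cap is not None and d > cap:
                return d
    return d


def realize_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Resolve each degenerate position of ``pattern`` uniformly at random."""
    out = []
    for p in pattern:
        options = IUPAC[p]
        out.append(options if len(options) == 1 else options[rng.integers(len(options))])
    return "".join(out)
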