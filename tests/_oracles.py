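"""Independent brute-force oracles, deliberately naive and library-free.

These re-derive expected values by exhaustive enumeration so that tests of
the package never check the implementation against itself.
"""

from __future__ import annotations

import itertools

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    "".join(c): _AMINO[i]
    for i, c in enumerate(itertools.product(_BASES, repeat=3))
}
STOPS = {c for c, aa in CODON_TABLE.items() if aa == "*"}


def translate(seq: str) -> str:
    """Translate complete codons; stops render as '*'."""
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


def orf_from(seq: str, tis: int) -> tuple[int | None, str]:
    """Walk codons from tis to the first stop; first residue forced to M."""
    pep = []
    pos = tis
    while pos + 3 <= len(seq):
        codon = seq[pos : pos + 3]
        if codon in STOPS:
            return pos, "M" + "".join(pep[1:]) if pep else ""
        pep.append(CODON_TABLE[codon])
        pos += 3
    return None, ("M" + "".join(pep[1:]) if pep else "")


def enumerate_orfs(seq: str, start_codons=("ATG",)) -> list[tuple[int, int | None, str]]:
    """Every start-to-stop span in all three frames: (tis, stop, peptide)."""
    out = []
    for tis in range(len(seq) - 2):
        if seq[tis : tis + 3] in start_codons:
            stop, pep = orf_from(seq, tis)
            out.append((tis, stop, pep))
    return out


def nb_tail_by_summation(x: int, mu: float, size: float, horizon: int = 100_000) -> float:
    """P(X >= x) for NB(mu, size) by direct pmf recursion up to a far horizon.

    pmf(0) = (size/(size+mu))**size; pmf(k+1) = pmf(k) * (k+size)/(k+1) * mu/(size+mu).
    Summing P(X < x) and subtracting from 1 keeps the tail accurate.
    """
    p = size / (size + mu)
    q = mu / (size + mu)
    pmf = p**size
    below = 0.0
    for k in range(x):
        below += pmf
        pmf *= (k + size) / (k + 1) * q
    return 1.0 - below


def bh_qvalues(pvals: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg step-up q-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q
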