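"""Low-level nucleotide utilities shared across modules.

Sequences are plain uppercase strings over {A,C,G,T,N}. Equal-length
comparisons are vectorised through a uint8 encoding; unequal-length
comparisons fall back to global alignment (Needleman-Wunsch via Biopython).
"""

from __future__ import annotations

import numpy as np
from Bio import Align

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNI", "TGCAYRSWMKVHDBNN")

#: IUPAC degeneracy map; inosine ("I") is treated as fully degenerate.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "I": "ACGT",
}

_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _ENC[ord(_b)] = _i
# 0 encodes "not a definite base" (N, gap, anything else) and is excluded
# from positional comparisons.


class UndefinedDistanceError(ValueError):
    """Raised when two sequences share zero comparable positions."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seqs: list[str], length: int | None = None) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    if length is None:
        length = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _ENC[arr].reshape(len(seqs), length)


def make_aligner() -> Align.PairwiseAligner:
    """Global aligner used for unequal-length sequence pairs."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # end gaps are free so that a short fragment aligns inside a longer one
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = make_aligner()


def _aligned_columns(a: str, b: str):
    """Yield (base_a, base_b) over non-end-gap columns of the best alignment."""
    alignment = _ALIGNER.align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    # trim end-gap columns: leading/trailing positions where either row is a gap
    start = 0
    end = len(sa)
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    return sa[start:end], sb[start:end]


def identity_overlap(a: str, b: str) -> tuple[float, int]:
    """Fraction of matching bases and number of compared columns.

    Equal-length inputs are compared positionally; positions where either
    sequence carries something other than A/C/G/T are excluded. Unequal
    lengths are globally aligned first; end-gap columns are excluded, and
    internal gap columns count as compared-but-mismatched overlap columns
    do not contribute matches.
    """
    if len(a) == len(b):
        ea, eb = encode([a]), encode([b])
        comparable = (ea > 0) & (eb > 0)
        n = int(comparable.sum())
        if n == 0:
            raise UndefinedDistanceError("no comparable positions")
        matches = int(((ea == eb) & comparable).sum())
        return matches / n, n
    sa, sb = _aligned_columns(a, b)
    pairs = [
        (x, y)
        for x, y in zip(sa, sb)
        if x in "ACGT" and y in "ACGT"
    ]
    if not pairs:
        raise UndefinedDistanceError("no comparable positions after alignment")
    matches = sum(x == y for x, y in pairs)
    return matches / len(pairs), len(pairs)


def p_dist(a: str, b: str) -> float:
    """Uncorrected pairwise distance with pairwise deletion of gaps/Ns."""
    ident, _ = identity_overlap(a, b)
    return 1.0 - ident


def pairwise_identity_matrix(queries: list[str], refs: list[str]) -> np.ndarray:
    """Identity of every query against every reference (vectorised when
    all sequences share one length)."""
    lens = {len(s) for s in queries} | {len(s) for s in refs}
    if len(lens) == 1:
        q = encode(queries)
        r = encode(refs)
        # chunk over queries to bound memory
        out = np.empty((len(queries), len(refs)))
        step = max(1, 2**24 // (r.size + 1))
        for i in range(0, len(queries), step):
            qc = q[i : i + step]
            comp = (qc[:, None, :] > 0) & (r[None, :, :] > 0)
            match = (qc[:, None, :] == r[None, :, :]) & comp
            n = comp.sum(axis=2)
            with np.errstate(invalid="ignore"):
                out[i : i + step] = match.sum(axis=2) / n
        return out
    out = np.empty((len(queries), len(refs)))
    for i, qs in enumerate(queries):
        for j, rs in enumerate(refs):
            out[i, j] = identity_overlap(qs, rs)[0]
    return out


def matches_iupac(pattern: str, text: str) -> int:
    """Count positions of `text` incompatible with IUPAC `pattern`.

    Degenerate positions (more than one allowed base) must be compatible;
    they are reported with a large sentinel so callers can enforce a
    zero-tolerance rule there. Returns the number of mismatches at
    non-degenerate positions, or -1 if a degenerate position is violated.
    """
    mismatches = 0
    for p, t in zip(pattern, text):
        allowed = IUPAC.get(p, p)
        if t not in allowed:
            if len(allowed) > 1:
                return -1
            mismatches += 1
    return mismatches
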