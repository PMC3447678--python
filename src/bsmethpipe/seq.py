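"""Low-level sequence utilities shared across the pipeline.

Sequences are handled as Python ``str`` at module boundaries and as
``numpy`` byte arrays (``dtype='S1'`` views / uint8 codes) internally where
vectorisation pays off.  Coordinates are 0-based half-open everywhere in
memory; text outputs are 1-based fully closed.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: integer codes for bases in count arrays
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: context codes
CONTEXTS = ("CG", "CHG", "CHH", "unknown")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Byte-code array (uint8 of ASCII) for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def base_code_array(seq: str) -> np.ndarray:
    """Map a sequence onto 0..3 codes (A,C,G,T); other characters -> -1."""
    arr = seq_to_array(seq)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def cytosine_strands(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of cytosine sites on the plus and the minus strand.

    A position carries a plus-strand cytosine when the reference base is C
    and a minus-strand cytosine when it is G (the minus strand has a C
    there).  The two are mutually exclusive.
    """
    arr = seq_to_array(seq)
    return arr == ord("C"), arr == ord("G")


def context_codes(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position methylation-context codes for both strands.

    Returns ``(ctx_plus, ctx_minus)`` int8 arrays with 0=CG, 1=CHG, 2=CHH,
    3=unknown; entries are meaningful only at the corresponding cytosine
    positions (see :func:`cytosine_strands`).  Context is read 5'->3' on the
    cytosine's own strand: CG if the next base is G, CHG if the base after
    next is G, CHH otherwise.  Sites within 2 bp of the contig end (on their
    strand) are 'unknown'.
    """
    arr = seq_to_array(seq)
    n = len(arr)
    ctx_p = np.full(n, 3, dtype=np.int8)
    ctx_m = np.full(n, 3, dtype=np.int8)
    if n >= 3:
        nxt = arr[1:-1]  # i+1 for i in 0..n-3
        nnx = arr[2:]  # i+2
        body = np.where(nxt == ord("G"), 0, np.where(nnx == ord("G"), 1, 2))
        ctx_p[: n - 2] = body
        # minus strand: next base is complement(arr[i-1]) == G  <=>  arr[i-1] == C
        prv = arr[1:-1]  # i-1 for i in 2..n-1
        ppv = arr[:-2]  # i-2
        body_m = np.where(prv == ord("C"), 0, np.where(ppv == ord("C"), 1, 2))
        ctx_m[2:] = body_m
    return ctx_p, ctx_m


def phred_to_qual(q: int) -> str:
    return chr(q + 33)


def qual_to_phred_array(qual: str) -> np.ndarray:
    return seq_to_array(qual).astype(np.int16) - 33
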