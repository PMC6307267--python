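"""Global pairwise alignment with affine gap penalties (Gotoh algorithm).

Defaults follow the classic DNA settings of the EMBOSS needle tool:
match +5, mismatch -4, gap open 10, gap extend 0.5, where a gap of
length k costs ``open + k * extend`` (the first gap base pays both).

Scores are computed in exact integer arithmetic (everything is scaled by
2 so the 0.5 extension is integral) and the traceback is deterministic:
ties are broken diagonal > up (gap in query) > left (gap in reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Alignment", "global_align"]

_NEG = -(10**9)


@dataclass(frozen=True)
class Alignment:
    """A global alignment: two equal-length rows over {A,C,G,T,-} and a score."""

    ref_row: str
    query_row: str
    score: float

    def __iter__(self):
        return iter((self.ref_row, self.query_row))


def global_align(
    reference: str,
    query: str,
    match: float = 5,
    mismatch: float = -4,
    gap_open: float = 10,
    gap_extend: float = 0.5,
) -> Alignment:
    """Needleman-Wunsch with affine gaps; see module docstring for defaults.

    ``gap_open`` and ``gap_extend`` are positive penalties.  All four
    parameters must be integral after scaling by 2 (halves are allowed).
    """
    if not reference or not query:
        raise ValueError("both sequences must be non-empty")

    params = []
    for v in (match, mismatch, gap_open, gap_extend):
        v2 = 2 * v
        if abs(v2 - round(v2)) > 1e-9:
            raise ValueError("scores must be multiples of 0.5")
        params.append(int(round(v2)))
    ma, mi, go, ge = params
    first = go + ge  # cost of opening a gap of length 1

    a, b = reference, query
    n, m = len(a), len(b)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)

    # M: ends in aligned pair; X: ends with gap in query (consumes ref, "up");
    # Y: ends with gap in reference (consumes query, "left")
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    ii = np.arange(1, n + 1, dtype=np.int64)
    jj = np.arange(1, m + 1, dtype=np.int64)
    X[1:, 0] = -(go + ge * ii)
    Y[0, 1:] = -(go + ge * jj)

    kext = np.arange(m + 1, dtype=np.int64) * ge
    for i in range(1, n + 1):
        sub = np.where(bb == ord(a[i - 1]), ma, mi)
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) - first, X[i - 1] - ge
        )
        # horizontal gap: Y[i,j] = max_{k<j}(base[k] + k*ge) - go - j*ge
        base = np.maximum(M[i], X[i])
        running = np.maximum.accumulate(base + kext)
        Y[i, 1:] = running[:-1] - go - kext[1:]
        Y[i, 0] = _NEG

    # deterministic traceback, preferring diagonal > up > left at every tie
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))  # argmax returns first max: M > X > Y
    score2 = finals[state]
    ra: list[str] = []
    qa: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            s = ma if a[i - 1] == b[j - 1] else mi
            target = M[i, j] - s
            ra.append(a[i - 1])
            qa.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            target = X[i, j]
            ra.append(a[i - 1])
            qa.append("-")
            i -= 1
            # predecessor costs differ by state
            if M[i, j] - first == target:
                state = 0
                continue
            if X[i, j] - ge == target:
                state = 1
                continue
            state = 2
            assert Y[i, j] - first == target
            continue
        else:
            target = Y[i, j]
            ra.append("-")
            qa.append(b[j - 1])
            j -= 1
            if M[i, j] - first == target:
                state = 0
                continue
            if X[i, j] - first == target:
                state = 1
                continue
            state = 2
            assert Y[i, j] - ge == target
            continue
        if M[i, j] == target:
            state = 0
        elif X[i, j] == target:
            state = 1
        else:
            state = 2
            assert Y[i, j] == target

    return Alignment("".join(reversed(ra)), "".join(reversed(qa)), float(score2) / 2.0)
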