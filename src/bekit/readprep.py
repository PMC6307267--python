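"""FASTQ input and paired-end overlap merging.

Paired reads are merged in the spirit of fastq-join: the reverse
complement of R2 is slid over R1 at every overlap length at or above a
minimum, the overlap with the smallest mismatch fraction wins (ties go
to the longest overlap), and the pair is accepted when that fraction is
at most ``max_mismatch_frac``.  Disagreeing overlap positions take the
higher-quality base (ties take R1's base) and the higher of the two
quality scores.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

__all__ = ["SequenceRead", "MergeRejection", "read_fastq", "write_fastq", "merge_pair", "merge_files"]

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRead:
    """One sequencing read: id, bases (ACGTN), and Phred quality scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )


@dataclass(frozen=True)
class MergeRejection:
    """Why a pair could not be merged: ``no_overlap`` or ``mismatch``."""

    reason: str


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream Phred+33 FASTQ records from a plain or gzipped file.

    Raises ``ValueError`` on a truncated record (file length not a
    multiple of four lines) or a bases/quality length mismatch, naming
    the 1-based record index.
    """
    with _open_text(path) as fh:
        record_idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            record_idx += 1
            lines = [header.rstrip("\n")]
            for _ in range(3):
                line = fh.readline()
                if not line:
                    raise ValueError(f"truncated FASTQ record at record {record_idx}")
                lines.append(line.rstrip("\n"))
            if not lines[0].startswith("@"):
                raise ValueError(f"record {record_idx}: header does not start with '@'")
            bases = lines[1].upper()
            quals = tuple(ord(c) - 33 for c in lines[3])
            if len(bases) != len(quals):
                raise ValueError(
                    f"record {record_idx}: sequence/quality length mismatch"
                )
            yield SequenceRead(read_id=lines[0][1:].split()[0], bases=bases, quals=quals)


def write_fastq(reads, path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ (gzipped when the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")


def _revcomp_read(r: SequenceRead) -> SequenceRead:
    return SequenceRead(r.read_id, r.bases.translate(_COMP)[::-1], r.quals[::-1])


def merge_pair(
    r1: SequenceRead,
    r2: SequenceRead,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.08,
) -> SequenceRead | MergeRejection:
    """Merge a read pair by overlap consensus, or return a :class:`MergeRejection`.

    Overlaps whose mismatch fraction exceeds 50% are treated as chance
    agreement (a pair with no true overlap disagrees at roughly three
    quarters of positions), so a pair with no such candidate is rejected
    as ``no_overlap``; a real overlap that is too noisy is ``mismatch``.
    """
    if not r1.bases or not r2.bases:
        return MergeRejection("no_overlap")
    rc2 = _revcomp_read(r2)
    max_len = min(len(r1.bases), len(rc2.bases))
    best: tuple[float, int] | None = None  # (mismatch fraction, overlap length)
    for L in range(min_overlap, max_len + 1):
        tail = r1.bases[len(r1.bases) - L :]
        head = rc2.bases[:L]
        mm = sum(1 for x, y in zip(tail, head) if x != y)
        frac = mm / L
        if frac > 0.5:
            continue
        if best is None or frac < best[0] or (frac == best[0] and L > best[1]):
            best = (frac, L)
    if best is None:
        return MergeRejection("no_overlap")
    frac, L = best
    if frac > max_mismatch_frac:
        return MergeRejection("mismatch")

    n1 = len(r1.bases)
    prefix_b = r1.bases[: n1 - L]
    prefix_q = list(r1.quals[: n1 - L])
    cons_b: list[str] = []
    cons_q: list[int] = []
    for k in range(L):
        b1, q1 = r1.bases[n1 - L + k], r1.quals[n1 - L + k]
        b2, q2 = rc2.bases[k], rc2.quals[k]
        if b1 == b2:
            cons_b.append(b1)
        elif q2 > q1:
            cons_b.append(b2)
        else:
            cons_b.append(b1)
        cons_q.append(max(q1, q2))
    suffix_b = rc2.bases[L:]
    suffix_q = list(rc2.quals[L:])
    return SequenceRead(
        read_id=r1.read_id,
        bases=prefix_b + "".join(cons_b) + suffix_b,
        quals=tuple(prefix_q + cons_q + suffix_q),
    )


def merge_files(
    r1_path: str | Path,
    r2_path: str | Path,
    min_overlap: int = 6,
    max_mismatch_frac: float = 0.08,
) -> tuple[list[SequenceRead], dict]:
    """Merge two FASTQ files pairwise; return merged reads and a report.

    The report counts ``pairs_in``, ``merged``, ``rejected_no_overlap``
    and ``rejected_mismatch``.
    """
    merged: list[SequenceRead] = []
    report = {"pairs_in": 0, "merged": 0, "rejected_no_overlap": 0, "rejected_mismatch": 0}
    for r1, r2 in zip(read_fastq(r1_path), read_fastq(r2_path)):
        report["pairs_in"] += 1
        res = merge_pair(r1, r2, min_overlap, max_mismatch_frac)
        if isinstance(res, MergeRejection):
            report[f"rejected_{res.reason}"] += 1
        else:
            merged.append(res)
            report["merged"] += 1
    return merged, report
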