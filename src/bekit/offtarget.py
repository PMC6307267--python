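"""Mismatch-bounded off-target scanning over a genome FASTA.

Every position on either strand of every record is tested: the PAM must
match its degenerate IUPAC pattern exactly (zero tolerance), and the
adjacent full-length protospacer may differ from the query spacer by at
most ``max_mismatches`` Hamming mismatches.  Sites overlapping non-ACGT
genome bases are excluded.  The scan is a vectorised sliding comparison —
no index structure — sized for desk-scale genomes.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .designer import TargetCandidate
from .registry import IUPAC_SETS, NucleaseProfile, PamSide

__all__ = ["OffTargetHit", "find_offtargets", "summarize_hits"]

logger = logging.getLogger(__name__)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic site: protospacer start (0-based, forward strand), strand,
    spacer mismatch count, and the site's spacer/PAM sequences."""

    seq_name: str
    position: int
    strand: str
    mismatches: int
    site_spacer: str
    site_pam: str


def _encode(seq: str) -> np.ndarray:
    """Encode ACGT as 0..3 and anything else as 4."""
    arr = np.full(len(seq), 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def _scan_strand(
    arr: np.ndarray,
    spacer: str,
    pattern: str,
    pam_side: PamSide,
    max_mm: int,
) -> list[tuple[int, int]]:
    """All (site_start, mismatches) on one encoded strand.

    ``site_start`` is the 0-based start of the full site (spacer+PAM in
    scan orientation: spacer first for a 3'-PAM, PAM first for a 5'-PAM).
    """
    S, P = len(spacer), len(pattern)
    site_len = S + P
    n = len(arr) - site_len + 1
    if n <= 0:
        return []
    pam_off = S if pam_side is PamSide.THREE_PRIME else 0
    sp_off = 0 if pam_side is PamSide.THREE_PRIME else P

    # PAM degeneracy match (positions with code 4 never match)
    pam_ok = np.ones(n, dtype=bool)
    for j, code in enumerate(pattern):
        allowed = np.zeros(5, dtype=bool)
        for b in IUPAC_SETS[code]:
            allowed[_BASE_CODE[b]] = True
        pam_ok &= allowed[arr[pam_off + j : pam_off + j + n]]

    # spacer Hamming distance; non-ACGT bases poison the site
    mm = np.zeros(n, dtype=np.int32)
    valid = np.ones(n, dtype=bool)
    for j, b in enumerate(spacer):
        col = arr[sp_off + j : sp_off + j + n]
        valid &= col != 4
        mm += col != _BASE_CODE[b]

    keep = pam_ok & valid & (mm <= max_mm)
    return [(int(i), int(mm[i])) for i in np.flatnonzero(keep)]


def find_offtargets(
    genome_path: str | Path,
    candidate: TargetCandidate | str,
    profile: NucleaseProfile,
    max_mismatches: int = 2,
) -> list[OffTargetHit]:
    """Scan a genome FASTA (plain or gzip) for off-target sites of a spacer.

    ``candidate`` may be a :class:`TargetCandidate` or a bare spacer string.
    Returns hits sorted by (seq_name, position, strand).
    """
    spacer = candidate.spacer if isinstance(candidate, TargetCandidate) else candidate
    if not spacer or any(c not in "ACGT" for c in spacer):
        raise ValueError("candidate spacer must be non-empty and ACGT-only")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")

    path = Path(genome_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")

    pattern = profile.pam_pattern
    site_len = len(spacer) + len(pattern)
    hits: list[OffTargetHit] = []
    for rec in records:
        seq = str(rec.seq).upper()
        L = len(seq)
        if L < site_len:
            logger.warning("record %s shorter than site length; skipped", rec.id)
            continue
        fwd = _encode(seq)
        rev_seq = reverse_complement(seq)
        rev = _encode(rev_seq)
        sp_in_site = 0 if profile.pam_side is PamSide.THREE_PRIME else len(pattern)
        for strand, arr, strand_seq in (("+", fwd, seq), ("-", rev, rev_seq)):
            for site_start, n_mm in _scan_strand(
                arr, spacer, pattern, profile.pam_side, max_mismatches
            ):
                sp_start = site_start + sp_in_site
                site_spacer = strand_seq[sp_start : sp_start + len(spacer)]
                if profile.pam_side is PamSide.THREE_PRIME:
                    pam_start = site_start + len(spacer)
                else:
                    pam_start = site_start
                site_pam = strand_seq[pam_start : pam_start + len(pattern)]
                if strand == "+":
                    position = sp_start
                else:
                    position = L - (sp_start + len(spacer))
                hits.append(
                    OffTargetHit(
                        seq_name=rec.id,
                        position=position,
                        strand=strand,
                        mismatches=n_mm,
                        site_spacer=site_spacer,
                        site_pam=site_pam,
                    )
                )
    hits.sort(key=lambda h: (h.seq_name, h.position, h.strand))
    return hits


def summarize_hits(spacer: str, hits: list[OffTargetHit]) -> dict:
    """Per-candidate summary: hit counts at 0, 1, 2 mismatches."""
    return {
        "candidate": spacer,
        "n_mm0": sum(1 for h in hits if h.mismatches == 0),
        "n_mm1": sum(1 for h in hits if h.mismatches == 1),
        "n_mm2": sum(1 for h in hits if h.mismatches == 2),
        "n_total": len(hits),
    }
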