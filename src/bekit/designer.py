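"""Guide enumeration for base editors.

Scans both strands of a query region for PAM matches, emits every
full-length protospacer candidate, and annotates each with the editable
bases that fall inside the editor's window, its 1-based position on the
input forward strand, and GC content.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .registry import (
    IUPAC_SETS,
    EditorPreset,
    NucleaseProfile,
    PamSide,
)

__all__ = [
    "QueryRegion",
    "TargetCandidate",
    "parse_sequence_input",
    "enumerate_targets",
    "gc_content",
    "filter_candidates",
    "candidates_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QueryRegion:
    """The input sequence to design against (uppercase IUPAC DNA)."""

    sequence: str
    origin_label: str = "raw"


@dataclass(frozen=True)
class TargetCandidate:
    """One designer hit.

    ``start``/``end`` are the 0-based half-open protospacer interval on the
    input forward strand; ``relative_position`` is the 1-based position of
    the protospacer 5' end on the forward strand.  ``editable`` lists
    (0-based spacer offset, base) pairs for occurrences of the editor's
    substrate base inside the editing window.
    """

    spacer: str
    pam: str
    strand: str
    start: int
    end: int
    editable: tuple[tuple[int, str], ...]
    relative_position: int
    gc_percent: float

    @property
    def has_editable(self) -> bool:
        return len(self.editable) > 0


def parse_sequence_input(text: str) -> QueryRegion:
    """Parse a raw IUPAC DNA string or FASTA text into a :class:`QueryRegion`.

    FASTA input (detected by a leading ``>``) uses the first record; raw
    input is stripped of whitespace and digits and uppercased.  Any
    character outside the IUPAC DNA alphabet is rejected with its position.
    """
    if not text or not text.strip():
        raise ValueError("empty sequence input")
    stripped = text.lstrip()
    if stripped.startswith(">"):
        records = list(SeqIO.parse(io.StringIO(stripped), "fasta"))
        if not records:
            raise ValueError("FASTA input contains no records")
        if len(records) > 1:
            logger.warning(
                "FASTA input has %d records; using the first (%s)",
                len(records), records[0].id,
            )
        seq = str(records[0].seq).upper()
        label = records[0].id or "fasta"
    else:
        seq = "".join(c for c in text if not c.isspace() and not c.isdigit()).upper()
        label = "raw"
    if not seq:
        raise ValueError("sequence empty after cleaning")
    for i, c in enumerate(seq):
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid character {c!r} at position {i}")
    return QueryRegion(sequence=seq, origin_label=label)


def gc_content(seq: str) -> float:
    """GC percentage of an ACGT string, in [0, 100]."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * sum(1 for c in seq if c in "GC") / len(seq)


def _degenerate_pam_match(pattern: str, window: str) -> bool:
    # query may itself carry degenerate codes; require the degeneracy sets
    # to intersect at every position
    for p, q in zip(pattern, window):
        if q not in IUPAC_SETS:
            return False
        if not (IUPAC_SETS[p] & IUPAC_SETS[q]):
            return False
    return True


def window_offsets(
    spacer_length: int,
    window: tuple[int, int],
    pam_side: PamSide,
) -> list[int]:
    """Map an editing window onto 0-based spacer offsets.

    For a 3'-PAM nuclease the window is counted in nt upstream of the PAM:
    distance d (1-based from the PAM-proximal spacer edge) is spacer offset
    ``spacer_length - d``.  For a 5'-PAM nuclease (Cpf1) the window counts
    from the PAM-proximal end, i.e. distance d is offset ``d - 1``.
    """
    proximal, distal = window
    if proximal < 1 or distal > spacer_length:
        raise ValueError(
            f"window {window} outside [1, {spacer_length}] for this spacer length"
        )
    if pam_side is PamSide.THREE_PRIME:
        offsets = [spacer_length - d for d in range(proximal, distal + 1)]
    else:
        offsets = [d - 1 for d in range(proximal, distal + 1)]
    return sorted(offsets)


def enumerate_targets(
    region: QueryRegion,
    profile: NucleaseProfile,
    editor: EditorPreset,
    spacer_length: int | None = None,
    window_override: tuple[int, int] | None = None,
) -> list[TargetCandidate]:
    """Enumerate all protospacer candidates on both strands of ``region``.

    At every position where the PAM pattern matches and a full-length
    spacer fits on the correct side, a candidate is emitted — including
    candidates with no editable base in the window (their ``editable``
    tuple is simply empty).  Spacers containing non-ACGT codes are skipped
    with a warning.  Output is sorted by start coordinate then strand.
    """
    if spacer_length is None:
        spacer_length = profile.spacer_length_default
    if not (profile.spacer_length_min <= spacer_length <= profile.spacer_length_max):
        raise ValueError(
            f"spacer_length {spacer_length} outside profile bounds "
            f"[{profile.spacer_length_min}, {profile.spacer_length_max}]"
        )
    window = window_override if window_override is not None else editor.window
    offsets = window_offsets(spacer_length, window, profile.pam_side)

    seq = region.sequence
    L = len(seq)
    plen = len(profile.pam_pattern)
    site_len = spacer_length + plen
    out: list[TargetCandidate] = []

    for strand, strand_seq in (("+", seq), ("-", reverse_complement(seq))):
        for pam_start in range(L - plen + 1):
            pam = strand_seq[pam_start:pam_start + plen]
            if not _degenerate_pam_match(profile.pam_pattern, pam):
                continue
            if profile.pam_side is PamSide.THREE_PRIME:
                sp_start = pam_start - spacer_length
                sp_end = pam_start
            else:
                sp_start = pam_start + plen
                sp_end = sp_start + spacer_length
            if sp_start < 0 or sp_end > L:
                continue
            spacer = strand_seq[sp_start:sp_end]
            if any(c not in "ACGT" for c in spacer):
                logger.warning(
                    "skipping candidate at %s:%d with non-ACGT spacer", strand, sp_start
                )
                continue
            if any(c not in "ACGT" for c in pam):
                logger.warning(
                    "skipping candidate at %s:%d with degenerate PAM bases", strand, sp_start
                )
                continue
            editable = tuple(
                (o, spacer[o]) for o in offsets if spacer[o] == editor.edited_base
            )
            if strand == "+":
                fwd_start, fwd_end = sp_start, sp_end
            else:
                fwd_start, fwd_end = L - sp_end, L - sp_start
            out.append(
                TargetCandidate(
                    spacer=spacer,
                    pam=pam,
                    strand=strand,
                    start=fwd_start,
                    end=fwd_end,
                    editable=editable,
                    relative_position=fwd_start + 1,
                    gc_percent=gc_content(spacer),
                )
            )
    out.sort(key=lambda c: (c.start, c.strand))
    return out


def filter_candidates(
    candidates: list[TargetCandidate],
    gc_min: float = 0.0,
    gc_max: float = 100.0,
    require_editable: bool = False,
) -> list[TargetCandidate]:
    """Filter candidates by GC range and (optionally) non-empty editable list."""
    if not (0.0 <= gc_min <= gc_max <= 100.0):
        raise ValueError("require 0 <= gc_min <= gc_max <= 100")
    return [
        c
        for c in candidates
        if gc_min <= c.gc_percent <= gc_max
        and (not require_editable or c.has_editable)
    ]


def candidates_to_frame(candidates: list[TargetCandidate]) -> pd.DataFrame:
    """Tabulate candidates for TSV/JSON export."""
    rows = [
        {
            "spacer": c.spacer,
            "pam": c.pam,
            "strand": c.strand,
            "start": c.start,
            "end": c.end,
            "relative_position": c.relative_position,
            "gc_percent": round(c.gc_percent, 2),
            "editable_bases": ";".join(f"{o}:{b}" for o, b in c.editable),
            "has_editable": c.has_editable,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "spacer", "pam", "strand", "start", "end",
            "relative_position", "gc_percent", "editable_bases", "has_editable",
        ],
    )
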