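"""Amplicon deep-sequencing quantification of base-editing outcomes.

The pipeline mirrors targeted amplicon analysis for base editors:

1. 15-nt *indicator* sequences are taken from both ends of the reference
   amplicon; reads (in either orientation) must contain both, each with
   at most one mismatch, and are trimmed to the indicator-to-indicator
   span.
2. Identical trimmed reads are tallied; sequences below a minimum
   frequency are discarded.
3. Each unique sequence is globally aligned to the reference and
   classified as wild type, insertion, deletion, or substitution from
   the gap pattern inside the editing window plus its flanks.
4. Substitution-class reads yield a per-position nucleotide table and
   the edited-base conversion spectrum (for a CBE: C→T, C→G, C→A); a
   control sample can be overlaid as negative-signed background rates.

All variant calls are scoped to the editing window extended by the
flanking windows: gaps or mismatches entirely outside that span leave a
read classified as wild type.  The ``intended`` flag additionally
requires an edited-base→product conversion inside the window proper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq, reverse_complement

from .align import Alignment, global_align
from .registry import EditorPreset
from .readprep import SequenceRead

__all__ = [
    "AnalysisConfig",
    "AlignedQuery",
    "RunSummary",
    "SubstitutionProfile",
    "AnalysisResult",
    "extract_indicators",
    "filter_by_indicators",
    "tally_unique",
    "classify",
    "summarize",
    "substitution_profile",
    "translate_frames",
    "control_overlay",
    "analyze",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
INDICATOR_LENGTH = 15


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the analyzer needs to know about one amplicon run.

    ``target_site`` is the protospacer followed by the PAM (5'→3' on the
    target strand); ``pam_length`` says how many of its trailing bases are
    PAM.  The editing window comes from the editor preset unless
    ``window_override`` is given (both in nt upstream of the PAM).
    ``flank_left``/``flank_right`` extend the analysis span on each side,
    in reference coordinates.  ``min_frequency`` is an absolute read
    count; reads below it are discarded after tallying.
    """

    reference: str
    target_site: str
    editor: EditorPreset
    target_strand: str = "+"
    pam_length: int = 3
    window_override: tuple[int, int] | None = None
    flank_left: int = 0
    flank_right: int = 0
    min_frequency: int = 1
    frame_offset: int = 0

    def __post_init__(self) -> None:
        ref = self.reference
        if any(c not in "ACGT" for c in ref):
            raise ValueError("reference must be ACGT-only")
        if self.target_strand not in "+-":
            raise ValueError("target_strand must be '+' or '-'")
        if self.min_frequency < 1:
            raise ValueError("min_frequency must be >= 1")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        if not (0 < self.pam_length < len(self.target_site)):
            raise ValueError("pam_length must leave a non-empty spacer")
        site = self.site_on_forward
        if self.reference.count(site) != 1:
            raise ValueError(
                "target_site must occur exactly once in the reference on the "
                f"declared strand (found {self.reference.count(site)})"
            )
        lo, hi = self.scope_span
        if lo < 0 or hi >= len(ref):
            raise ValueError("window plus flanks must lie inside the reference")

    @property
    def spacer(self) -> str:
        return self.target_site[: -self.pam_length]

    @property
    def site_on_forward(self) -> str:
        """The target site as it reads on the reference forward strand."""
        if self.target_strand == "+":
            return self.target_site
        return reverse_complement(self.target_site)

    @property
    def window(self) -> tuple[int, int]:
        return self.window_override or self.editor.window

    @property
    def window_positions(self) -> tuple[int, ...]:
        """Reference coordinates (0-based) of the editing-window positions."""
        site_start = self.reference.index(self.site_on_forward)
        S = len(self.spacer)
        proximal, distal = self.window
        if proximal < 1 or distal > S:
            raise ValueError(f"window {self.window} outside [1, {S}]")
        positions = []
        for d in range(proximal, distal + 1):
            offset = S - d  # 0-based offset within the spacer, 5'->3'
            if self.target_strand == "+":
                positions.append(site_start + offset)
            else:
                positions.append(site_start + self.pam_length + (S - 1 - offset))
        return tuple(sorted(positions))

    @property
    def scope_span(self) -> tuple[int, int]:
        """Inclusive reference span of window ± flanks (variant-call scope)."""
        wp = self.window_positions
        return (min(wp) - self.flank_left, max(wp) + self.flank_right)

    def edited_ref_base(self) -> str:
        """The editor's substrate base as it appears on the forward strand."""
        b = self.editor.edited_base
        return b if self.target_strand == "+" else _COMP[b]

    def product_ref_bases(self) -> frozenset[str]:
        """Intended product bases as they appear on the forward strand."""
        ps = self.editor.product_bases
        if self.target_strand == "+":
            return frozenset(ps)
        return frozenset(_COMP[p] for p in ps)


@dataclass(frozen=True)
class AlignedQuery:
    """One unique read aligned to the reference, with its class label."""

    ref_row: str
    query_row: str
    count: int
    label: str
    intended: bool


@dataclass(frozen=True)
class RunSummary:
    """The analyzer's 9-field statistics record."""

    total_sequences: int
    with_both_indicators: int
    above_min_frequency: int
    wt: int
    insertions: int
    deletions: int
    with_substitution: int
    intended_in_window: int
    intended_rate: float

    def to_dict(self) -> dict:
        return {
            "total_sequences": self.total_sequences,
            "with_both_indicators": self.with_both_indicators,
            "above_min_frequency": self.above_min_frequency,
            "wt": self.wt,
            "insertions": self.insertions,
            "deletions": self.deletions,
            "with_substitution": self.with_substitution,
            "intended_in_window": self.intended_in_window,
            "intended_rate": self.intended_rate,
        }


@dataclass(frozen=True)
class SubstitutionProfile:
    """Per-position nucleotide percentages and conversion rates.

    ``positions`` are reference coordinates spanning window ± flanks.
    ``base_percent[i]`` maps each of A/C/G/T to its percentage among
    substitution-class reads covering position ``positions[i]`` gap-free;
    ``transition_rate[i]`` maps each conversion (keyed on the target
    strand, e.g. ``"C>T"``) to its fraction of covering reads, and is
    empty at positions whose reference base is not the editor substrate.
    ``control_rate`` carries the control sample's rates as negative
    display values; ``background`` flags positions where the control
    rate reaches the treated rate.
    """

    positions: tuple[int, ...]
    ref_bases: tuple[str, ...]
    coverage: tuple[int, ...]
    base_percent: tuple[dict, ...]
    transition_rate: tuple[dict, ...]
    control_rate: tuple[dict, ...] | None = None
    background: tuple[bool, ...] | None = None
    empty: bool = False


@dataclass(frozen=True)
class AnalysisResult:
    """Everything one analyzer run produces."""

    summary: RunSummary
    aligned: tuple[AlignedQuery, ...]
    profile: SubstitutionProfile
    frames: dict[int, str]
    per_product_rates: dict[str, float]
    drop_counts: dict[str, int]


# ---------------------------------------------------------------------------
# stage 1: indicator filtering


def extract_indicators(reference: str | AnalysisConfig) -> tuple[str, str]:
    """The 15-nt indicator sequences at both ends of the reference."""
    ref = reference.reference if isinstance(reference, AnalysisConfig) else reference
    if len(ref) < 2 * INDICATOR_LENGTH:
        raise ValueError(
            f"reference too short ({len(ref)} nt) for two {INDICATOR_LENGTH}-nt indicators"
        )
    return ref[:INDICATOR_LENGTH], ref[-INDICATOR_LENGTH:]


def _best_indicator_pair(
    s: str, left: str, right: str, max_mm: int
) -> tuple[int, int, int] | None:
    """Best (l_start, r_start, total_mm) with each indicator at <= max_mm
    mismatches and the right indicator starting after the left one ends."""
    k = len(left)
    n = len(s)
    if n < 2 * k:
        return None
    # fast path: exact occurrences cannot be beaten
    li = s.find(left)
    if li != -1:
        ri = s.find(right, li + k)
        if ri != -1:
            return (li, ri, 0)
    lefts: list[tuple[int, int]] = []
    rights: list[tuple[int, int]] = []
    for o in range(n - k + 1):
        mm_l = mm_r = 0
        win = s[o : o + k]
        for a, b in zip(win, left):
            if a != b:
                mm_l += 1
                if mm_l > max_mm:
                    break
        if mm_l <= max_mm:
            lefts.append((o, mm_l))
        for a, b in zip(win, right):
            if a != b:
                mm_r += 1
                if mm_r > max_mm:
                    break
        if mm_r <= max_mm:
            rights.append((o, mm_r))
    best: tuple[int, int, int] | None = None
    for lo, lmm in lefts:
        for ro, rmm in rights:
            if ro < lo + k:
                continue
            total = lmm + rmm
            if best is None or total < best[2]:
                best = (lo, ro, total)
    return best


def filter_by_indicators(
    reads: Iterable[SequenceRead | str],
    left: str,
    right: str,
    max_mm: int = 1,
) -> tuple[list[str], int]:
    """Keep reads containing both indicators (<= ``max_mm`` mismatches each).

    Each read is tried in both orientations; the orientation with the
    lower total indicator mismatch wins (tie → forward).  Kept reads are
    trimmed to the span from the left indicator's start through the right
    indicator's end.  Returns ``(trimmed_strings, n_dropped)``.
    """
    kept: list[str] = []
    dropped = 0
    k = len(left)
    for read in reads:
        s = read.bases if isinstance(read, SequenceRead) else read
        s = s.upper()
        fwd = _best_indicator_pair(s, left, right, max_mm)
        if fwd is not None and fwd[2] == 0:
            best, seq = fwd, s
        else:
            rc = reverse_complement(s)
            rev = _best_indicator_pair(rc, left, right, max_mm)
            if fwd is not None and (rev is None or fwd[2] <= rev[2]):
                best, seq = fwd, s
            elif rev is not None:
                best, seq = rev, rc
            else:
                dropped += 1
                continue
        lo, ro, _ = best
        kept.append(seq[lo : ro + k])
    return kept, dropped


# ---------------------------------------------------------------------------
# stage 2: tally


def tally_unique(queries: Iterable[str], min_frequency: int = 1) -> list[tuple[str, int]]:
    """Unique sequences with count >= ``min_frequency``, count-descending
    (ties broken lexicographically for determinism)."""
    if min_frequency < 1:
        raise ValueError("min_frequency must be >= 1")
    counts: dict[str, int] = {}
    for q in queries:
        counts[q] = counts.get(q, 0) + 1
    items = [(s, c) for s, c in counts.items() if c >= min_frequency]
    items.sort(key=lambda sc: (-sc[1], sc[0]))
    return items


# ---------------------------------------------------------------------------
# stage 3: alignment + classification


def _column_coords(ref_row: str) -> list[int]:
    """Reference coordinate per alignment column.

    Aligned reference bases carry their own 0-based position; a reference
    gap (insertion) carries the position of the next reference base, so an
    insertion between positions p-1 and p is attributed to p.
    """
    coords = []
    pos = 0
    for c in ref_row:
        coords.append(pos)
        if c != "-":
            pos += 1
    return coords


def classify(aligned: Alignment | tuple[str, str], config: AnalysisConfig) -> tuple[str, bool]:
    """Four-way classification of one aligned query.

    Gap columns inside window ± flanks make the read an insertion (more
    reference-row hyphens) or deletion (more query-row hyphens; ties are
    deletions).  Otherwise a mismatch inside the span makes it a
    substitution; otherwise it is wild type.  ``intended`` requires a
    substitution read with an edited-base→product column inside the
    window proper.
    """
    if isinstance(aligned, Alignment):
        ref_row, query_row = aligned.ref_row, aligned.query_row
    else:
        ref_row, query_row = aligned
    coords = _column_coords(ref_row)
    lo, hi = config.scope_span
    in_scope = [lo <= p <= hi for p in coords]

    ins_gaps = sum(
        1 for i, c in enumerate(ref_row) if c == "-" and in_scope[i]
    )
    del_gaps = sum(
        1 for i, c in enumerate(query_row) if c == "-" and in_scope[i] and ref_row[i] != "-"
    )
    if ins_gaps or del_gaps:
        label = "insertion" if ins_gaps > del_gaps else "deletion"
        return label, False

    has_sub = any(
        in_scope[i]
        and ref_row[i] != "-"
        and query_row[i] != "-"
        and ref_row[i] != query_row[i]
        for i in range(len(ref_row))
    )
    if not has_sub:
        return "wt", False

    window = set(config.window_positions)
    substrate = config.edited_ref_base()
    products = config.product_ref_bases()
    intended = any(
        coords[i] in window
        and ref_row[i] == substrate
        and query_row[i] != "-"
        and query_row[i] in products
        for i in range(len(ref_row))
        if ref_row[i] != "-"
    )
    return "substitution", intended


def summarize(
    aligned: Sequence[AlignedQuery],
    total_sequences: int,
    with_both_indicators: int,
) -> RunSummary:
    """Fill the 9-field summary from classified queries and filter counters."""
    above = sum(q.count for q in aligned)
    if above == 0:
        raise ValueError("no analyzable reads above the minimum frequency")
    by = {"wt": 0, "insertion": 0, "deletion": 0, "substitution": 0}
    intended = 0
    for q in aligned:
        by[q.label] += q.count
        if q.intended:
            intended += q.count
    return RunSummary(
        total_sequences=total_sequences,
        with_both_indicators=with_both_indicators,
        above_min_frequency=above,
        wt=by["wt"],
        insertions=by["insertion"],
        deletions=by["deletion"],
        with_substitution=by["substitution"],
        intended_in_window=intended,
        intended_rate=intended / above,
    )


# ---------------------------------------------------------------------------
# stage 4: per-position tables


def _ref_pos_bases(ref_row: str, query_row: str) -> dict[int, str]:
    """Map reference position -> query base for gap-free aligned columns."""
    out: dict[int, str] = {}
    pos = 0
    for rc, qc in zip(ref_row, query_row):
        if rc != "-":
            if qc != "-":
                out[pos] = qc
            pos += 1
    return out


def substitution_profile(
    aligned: Sequence[AlignedQuery],
    config: AnalysisConfig,
    population: str = "substitution",
) -> SubstitutionProfile:
    """Per-position base percentages and conversion spectrum.

    By default only substitution-class reads contribute (the table the
    substitution view shows); ``population="all"`` tabulates every
    analyzed read instead (the whole-population variant view).  At each
    position the denominator is the (count-weighted) number of
    contributing reads covering it gap-free.
    """
    lo, hi = config.scope_span
    positions = tuple(range(lo, hi + 1))
    ref_bases = tuple(config.reference[p] for p in positions)
    substrate = config.edited_ref_base()
    prods = sorted(config.product_ref_bases()) if config.editor.edited_base else []
    if population == "substitution":
        pool = [q for q in aligned if q.label == "substitution"]
    elif population == "all":
        pool = list(aligned)
    else:
        raise ValueError("population must be 'substitution' or 'all'")

    # conversion keys are reported in target-strand terms (e.g. C>T)
    def _target_strand_base(ref_fwd_base: str) -> str:
        return ref_fwd_base if config.target_strand == "+" else _COMP[ref_fwd_base]

    cover = [0] * len(positions)
    base_counts = [{b: 0 for b in "ACGT"} for _ in positions]
    for q in pool:
        seen = _ref_pos_bases(q.ref_row, q.query_row)
        for i, p in enumerate(positions):
            b = seen.get(p)
            if b is not None and b in "ACGT":
                cover[i] += q.count
                base_counts[i][b] += q.count

    base_percent = []
    transition_rate = []
    for i, p in enumerate(positions):
        if cover[i]:
            base_percent.append(
                {b: 100.0 * base_counts[i][b] / cover[i] for b in "ACGT"}
            )
        else:
            # uncovered position: fall back to the reference base
            base_percent.append({b: (100.0 if b == ref_bases[i] else 0.0) for b in "ACGT"})
        tr: dict[str, float] = {}
        if ref_bases[i] == substrate:
            for prod_fwd in sorted(config.product_ref_bases()):
                key = f"{config.editor.edited_base}>{_target_strand_base(prod_fwd)}"
                tr[key] = (base_counts[i][prod_fwd] / cover[i]) if cover[i] else 0.0
        transition_rate.append(tr)

    return SubstitutionProfile(
        positions=positions,
        ref_bases=ref_bases,
        coverage=tuple(cover),
        base_percent=tuple(base_percent),
        transition_rate=tuple(transition_rate),
        empty=not pool,
    )


def translate_frames(region_sequence: str, frame_offset: int | None = None) -> dict[int, str]:
    """Standard-code translation of a region in each of the three frames.

    Trailing partial codons are dropped and stops render as ``*``.  When
    ``frame_offset`` is given only that frame is returned (still keyed by
    its offset).
    """
    if len(region_sequence) < 3:
        raise ValueError("region must be at least one codon long")
    frames = {}
    offsets = (frame_offset,) if frame_offset is not None else (0, 1, 2)
    for f in offsets:
        sub = region_sequence[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        frames[f] = str(Seq(sub).translate()) if sub else ""
    return frames


def control_overlay(
    treated: SubstitutionProfile, control: SubstitutionProfile
) -> SubstitutionProfile:
    """Attach a control run's conversion rates as negative display values.

    Positions where the control's rate reaches the treated rate (and is
    non-zero) are flagged as background; counts are never subtracted.
    """
    if treated.positions != control.positions:
        raise ValueError("treated and control profiles cover different positions")
    control_rates = []
    background = []
    for tr, cr in zip(treated.transition_rate, control.transition_rate):
        control_rates.append({k: -v for k, v in cr.items()})
        background.append(
            any(cr.get(k, 0.0) > 0 and cr.get(k, 0.0) >= tv for k, tv in tr.items())
        )
    return replace(
        treated, control_rate=tuple(control_rates), background=tuple(background)
    )


# ---------------------------------------------------------------------------
# the whole pipeline


def analyze(
    reads: Iterable[SequenceRead | str],
    config: AnalysisConfig,
    control_reads: Iterable[SequenceRead | str] | None = None,
) -> AnalysisResult:
    """Run the full pipeline on pre-merged reads.

    ``control_reads``, when given, are analyzed with the same settings and
    overlaid on the substitution profile as negative background rates.
    """
    reads = list(reads)
    total = len(reads)
    left, right = extract_indicators(config.reference)
    trimmed, dropped = filter_by_indicators(reads, left, right)
    tallied = tally_unique(trimmed, config.min_frequency)
    below_min = len(trimmed) - sum(c for _, c in tallied)

    aligned: list[AlignedQuery] = []
    for seq, count in tallied:
        aln = global_align(config.reference, seq)
        label, intended = classify(aln, config)
        aligned.append(
            AlignedQuery(aln.ref_row, aln.query_row, count, label, intended)
        )

    summary = summarize(aligned, total, len(trimmed))
    profile = substitution_profile(aligned, config)

    # headline rate per product base so e.g. a C-to-T rate is recoverable
    window = set(config.window_positions)
    substrate = config.edited_ref_base()
    per_product: dict[str, float] = {}
    for prod_fwd in sorted(config.product_ref_bases()):
        n_prod = 0
        for q in aligned:
            if q.label != "substitution":
                continue
            seen = _ref_pos_bases(q.ref_row, q.query_row)
            if any(
                p in window and config.reference[p] == substrate and seen.get(p) == prod_fwd
                for p in window
            ):
                n_prod += q.count
        tgt = prod_fwd if config.target_strand == "+" else _COMP[prod_fwd]
        per_product[f"{config.editor.edited_base}_to_{tgt}_rate"] = (
            n_prod / summary.above_min_frequency
        )

    if control_reads is not None:
        ctrl_result = analyze(control_reads, config)
        profile = control_overlay(profile, ctrl_result.profile)

    lo, hi = config.scope_span
    frames = translate_frames(config.reference[lo : hi + 1])

    return AnalysisResult(
        summary=summary,
        aligned=tuple(aligned),
        profile=profile,
        frames=frames,
        per_product_rates=per_product,
        drop_counts={"no_indicators": dropped, "below_min_frequency": below_min},
    )
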