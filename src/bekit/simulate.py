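"""Synthetic data with known ground truth.

Two generators back the whole test surface: toy genomes with off-target
sites planted at exact mismatch counts, and simulated base-edited
amplicon reads with per-read truth labels.  Randomness comes exclusively
from ``numpy.random.default_rng`` (PCG64) seeded explicitly, so identical
seeds give identical bytes on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

from .analyzer import AnalysisConfig
from .readprep import SequenceRead
from .registry import IUPAC_SETS

__all__ = [
    "PlantedSite",
    "SimulationTruth",
    "ReadLabel",
    "make_toy_genome",
    "make_reference_with_site",
    "simulate_edited_reads",
    "split_pairs",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for one planted off-target site: where it went and how
    many spacer mismatches were introduced."""

    seq_name: str
    spacer_start: int  # 0-based protospacer start on the forward strand
    strand: str
    mismatches: int
    site_spacer: str
    site_pam: str


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _concretize_pam(rng: np.random.Generator, pattern: str) -> str:
    """Draw one concrete ACGT realisation of a degenerate PAM pattern."""
    return "".join(sorted(IUPAC_SETS[c])[rng.integers(0, len(IUPAC_SETS[c]))] for c in pattern)


def make_toy_genome(
    seed: int,
    n_records: int,
    record_length: int,
    planted_sites: list[tuple[str, str, int, str]],
) -> tuple[str, list[PlantedSite]]:
    """Random FASTA with off-target sites planted at exact mismatch counts.

    Each planted site is ``(spacer, pam, mismatches, strand)``; the PAM may
    be degenerate (a concrete realisation is drawn), the requested number
    of spacer positions is mutated to different bases, and the site is
    written into a round-robin record at a deterministic, non-overlapping
    coordinate.  PAMs are assumed to lie 3' of the spacer.  Returns the
    FASTA text and the truth table.
    """
    rng = np.random.default_rng(seed)
    records = [list(_random_dna(rng, record_length)) for _ in range(n_records)]
    names = [f"chr{i + 1}" for i in range(n_records)]
    truth: list[PlantedSite] = []
    cursor = [10] * n_records  # next free coordinate per record, with margin

    for idx, (spacer, pam_pattern, n_mm, strand) in enumerate(planted_sites):
        if n_mm < 0:
            raise ValueError("mismatch counts must be >= 0")
        pam = _concretize_pam(rng, pam_pattern)
        site_spacer = list(spacer)
        positions = rng.choice(len(spacer), size=n_mm, replace=False)
        for p in positions:
            alts = [b for b in "ACGT" if b != spacer[p]]
            site_spacer[p] = alts[rng.integers(0, 3)]
        site = "".join(site_spacer) + pam
        rec = idx % n_records
        pos = cursor[rec]
        if pos + len(site) > record_length - 10:
            raise ValueError("site does not fit in record")
        cursor[rec] = pos + len(site) + 25
        if strand == "+":
            records[rec][pos : pos + len(site)] = list(site)
            spacer_start = pos
        else:
            rc = reverse_complement(site)
            records[rec][pos : pos + len(site)] = list(rc)
            # on the forward strand the revcomp'd PAM comes first
            spacer_start = pos + len(pam)
        truth.append(
            PlantedSite(
                seq_name=names[rec],
                spacer_start=spacer_start,
                strand=strand,
                mismatches=n_mm,
                site_spacer="".join(site_spacer),
                site_pam=pam,
            )
        )

    fasta = "".join(
        f">{name}\n{''.join(rec)}\n" for name, rec in zip(names, records)
    )
    return fasta, truth


def make_reference_with_site(
    seed: int,
    length: int = 120,
    spacer_length: int = 20,
    pam: str = "TGG",
    site_start: int = 40,
) -> tuple[str, str]:
    """A random amplicon reference carrying one protospacer+PAM site.

    Returns ``(reference, target_site)`` with the site on the forward
    strand starting at ``site_start``.
    """
    rng = np.random.default_rng(seed)
    site_len = spacer_length + len(pam)
    if site_start + site_len > length:
        raise ValueError("site does not fit in the reference")
    ref = list(_random_dna(rng, length))
    ref[site_start + spacer_length : site_start + site_len] = list(pam)
    # guarantee a CBE substrate at 15 nt upstream of the PAM (mid-window
    # for the common presets)
    ref[site_start + spacer_length - 15] = "C"
    reference = "".join(ref)
    target_site = reference[site_start : site_start + site_len]
    # the analyzer requires a unique site; regenerate on the (vanishingly
    # rare) collision
    if reference.count(target_site) != 1:
        return make_reference_with_site(seed + 1, length, spacer_length, pam, site_start)
    return reference, target_site


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth generative parameters for an amplicon simulation.

    ``intended`` and ``bystander`` are tuples of
    ``(ref_position, probability, alternate_base)`` applied independently
    per read (bases in forward-reference orientation).  Indels occur with
    ``indel_prob`` at the nominal cut site (3 bp 5' of the PAM), with
    geometric sizes of mean ``indel_mean_size``; sequencing errors hit
    each base independently at ``error_rate``.
    """

    n_reads: int = 2000
    seed: int = 0
    intended: tuple[tuple[int, float, str], ...] = ()
    bystander: tuple[tuple[int, float, str], ...] = ()
    indel_prob: float = 0.0
    indel_mean_size: float = 3.0
    error_rate: float = 0.0
    phred: int = 30

    def __post_init__(self) -> None:
        for pos, p, alt in self.intended + self.bystander:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not (0.0 <= self.indel_prob <= 1.0 and 0.0 <= self.error_rate <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")


@dataclass(frozen=True)
class ReadLabel:
    """Per-read truth: what the simulator actually did to this read."""

    read_id: str
    intended_edited: tuple[int, ...]
    bystander_edited: tuple[int, ...]
    indel: str | None  # None, "insertion" or "deletion"
    indel_size: int
    n_errors: int
    expected_label: str  # class the analyzer should assign at zero error


def _cut_position(config: AnalysisConfig) -> int:
    """Nominal blunt-cut reference coordinate: 3 bp 5' of the PAM."""
    site_start = config.reference.index(config.site_on_forward)
    S = len(config.spacer)
    if config.target_strand == "+":
        return site_start + S - 3
    return site_start + config.pam_length + 3


def simulate_edited_reads(
    config: AnalysisConfig,
    truth: SimulationTruth,
) -> tuple[list[SequenceRead], list[ReadLabel]]:
    """Draw reads from the reference under the truth model.

    Substitution edits are applied independently, then (with
    ``indel_prob``) an insertion or deletion of geometric size at the cut
    site, then uniform sequencing errors.  The expected analyzer class is
    recorded per read, scoped to the window ± flanks exactly as the
    analyzer scopes it.
    """
    rng = np.random.default_rng(truth.seed)
    ref = config.reference
    cut = _cut_position(config)
    lo, hi = config.scope_span
    reads: list[SequenceRead] = []
    labels: list[ReadLabel] = []

    for i in range(truth.n_reads):
        frag = list(ref)
        hit_intended: list[int] = []
        hit_bystander: list[int] = []
        for pos, p, alt in truth.intended:
            if rng.random() < p:
                frag[pos] = alt
                hit_intended.append(pos)
        for pos, p, alt in truth.bystander:
            if rng.random() < p:
                frag[pos] = alt
                hit_bystander.append(pos)

        indel_kind: str | None = None
        indel_size = 0
        if truth.indel_prob and rng.random() < truth.indel_prob:
            indel_size = int(rng.geometric(1.0 / truth.indel_mean_size))
            if rng.random() < 0.5:
                indel_kind = "insertion"
                ins = _random_dna(rng, indel_size)
                frag[cut:cut] = list(ins)
            else:
                indel_kind = "deletion"
                del frag[cut : cut + indel_size]

        n_err = 0
        if truth.error_rate:
            for j in range(len(frag)):
                if rng.random() < truth.error_rate:
                    alts = [b for b in "ACGT" if b != frag[j]]
                    frag[j] = alts[rng.integers(0, 3)]
                    n_err += 1

        # expected analyzer class, applying the analyzer's scoping rule:
        # variation entirely outside window ± flanks leaves the read WT
        indel_in_scope = False
        if indel_kind == "deletion":
            indel_in_scope = cut <= hi and cut + indel_size - 1 >= lo
        elif indel_kind == "insertion":
            indel_in_scope = lo <= cut <= hi
        deleted = (
            range(cut, cut + indel_size) if indel_kind == "deletion" else range(0)
        )
        subs_in_scope = any(
            lo <= p <= hi and p not in deleted for p in hit_intended + hit_bystander
        )
        if indel_in_scope:
            expected = indel_kind
        elif subs_in_scope:
            expected = "substitution"
        else:
            expected = "wt"

        read_id = f"sim_{i}"
        bases = "".join(frag)
        reads.append(
            SequenceRead(read_id, bases, tuple([truth.phred] * len(bases)))
        )
        labels.append(
            ReadLabel(
                read_id=read_id,
                intended_edited=tuple(hit_intended),
                bystander_edited=tuple(hit_bystander),
                indel=indel_kind,
                indel_size=indel_size,
                n_errors=n_err,
                expected_label=expected,
            )
        )
    return reads, labels


def split_pairs(
    reads: list[SequenceRead],
    read_length: int | None = None,
) -> tuple[list[SequenceRead], list[SequenceRead]]:
    """Turn fragments into overlapping R1/R2 pairs.

    R1 is the fragment's 5' prefix; R2 is the reverse complement of its
    3' suffix.  The default read length guarantees a generous overlap, so
    error-free pairs merge back to the fragment exactly.
    """
    r1s, r2s = [], []
    for r in reads:
        L = read_length or (len(r.bases) // 2 + 15)
        L = min(L, len(r.bases))
        r1s.append(SequenceRead(r.read_id, r.bases[:L], r.quals[:L]))
        tail_b = r.bases[-L:]
        tail_q = r.quals[-L:]
        r2s.append(
            SequenceRead(
                r.read_id,
                reverse_complement(tail_b),
                tuple(reversed(tail_q)),
            )
        )
    return r1s, r2s
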