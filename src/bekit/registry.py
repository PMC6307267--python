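"""Built-in nuclease/PAM profiles, base-editor presets, and IUPAC matching.

The registry holds the CRISPR effectors the designer knows about: the
SpCas9 family and its PAM-relaxed variants, the compact orthologues
(StCas9, CjCas9, SaCas9), and the two Cpf1 (Cas12a) enzymes whose PAM
sits 5' of the protospacer.  Each profile records the degenerate PAM
pattern in IUPAC nucleotide codes, which side of the protospacer the PAM
abuts, and the allowed spacer-length range.

Editor presets describe what a base editor does chemically: which base
it deaminates (C for CBEs, A for ABEs), which product bases count as an
intended conversion, and the editing window expressed in nucleotides
upstream of the PAM (1-based distance from the PAM-proximal protospacer
edge).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import Enum

__all__ = [
    "PamSide",
    "NucleaseProfile",
    "EditorPreset",
    "IUPAC_SETS",
    "iupac_matches",
    "builtin_profiles",
    "builtin_editors",
    "get_profile",
    "get_editor",
    "registry_json",
]


class PamSide(str, Enum):
    """Which side of the protospacer the PAM sequence abuts."""

    THREE_PRIME = "three_prime"
    FIVE_PRIME = "five_prime"


#: Degeneracy sets for the 15 IUPAC nucleotide codes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class NucleaseProfile:
    """A Cas effector: its PAM pattern, PAM side, and spacer-length bounds."""

    name: str
    pam_pattern: str
    pam_side: PamSide = PamSide.THREE_PRIME
    spacer_length_default: int = 20
    spacer_length_min: int = 15
    spacer_length_max: int = 25

    def __post_init__(self) -> None:
        if not self.pam_pattern:
            raise ValueError("pam_pattern must be non-empty")
        bad = set(self.pam_pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"pam_pattern contains non-IUPAC codes: {sorted(bad)}")
        if not (self.spacer_length_min <= self.spacer_length_default <= self.spacer_length_max):
            raise ValueError("spacer_length_min <= default <= max violated")
        if self.spacer_length_min < 15 or self.spacer_length_max > 25:
            raise ValueError("spacer lengths must lie within [15, 25]")


@dataclass(frozen=True)
class EditorPreset:
    """A base-editor chemistry: edited base, products, and editing window.

    ``window_proximal``/``window_distal`` are 1-based distances upstream of
    the PAM; e.g. BE3's window of 13-17 nt upstream of the PAM is
    ``(proximal=13, distal=17)``.
    """

    name: str
    edited_base: str
    product_bases: frozenset[str]
    window_proximal: int
    window_distal: int

    def __post_init__(self) -> None:
        if self.edited_base not in ("C", "A"):
            raise ValueError("edited_base must be C (CBE) or A (ABE)")
        if self.window_proximal > self.window_distal:
            raise ValueError("window_proximal must be <= window_distal")
        if self.edited_base == "C" and not self.product_bases <= frozenset("AGT"):
            raise ValueError("CBE product bases must be a subset of {A,G,T}")
        if self.edited_base == "A" and self.product_bases != frozenset("G"):
            raise ValueError("ABE product bases must be exactly {G}")

    @property
    def window(self) -> tuple[int, int]:
        return (self.window_proximal, self.window_distal)


def iupac_matches(pattern: str, sequence: str) -> bool:
    """True iff ``sequence`` (A/C/G/T) matches the IUPAC ``pattern`` positionwise.

    Raises ``ValueError`` on length mismatch or characters outside the
    IUPAC alphabet (pattern) / ACGT (sequence).
    """
    if len(pattern) != len(sequence):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(sequence)}"
        )
    for i, (p, s) in enumerate(zip(pattern, sequence)):
        try:
            allowed = IUPAC_SETS[p]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {p!r} at pattern position {i}") from None
        if s not in "ACGT":
            raise ValueError(f"invalid base {s!r} at sequence position {i}")
        if s not in allowed:
            return False
    return True


_PROFILES: tuple[NucleaseProfile, ...] = (
    NucleaseProfile("SpCas9", "NGG"),
    NucleaseProfile("SpCas9-VQR", "NGAN"),
    NucleaseProfile("SpCas9-EQR", "NGAG"),
    NucleaseProfile("SpCas9-VRER", "NGCG"),
    NucleaseProfile("xCas9-NGR", "NGR"),
    NucleaseProfile("xCas9-NG", "NG"),
    NucleaseProfile("StCas9", "NNAGAAW"),
    NucleaseProfile("CjCas9", "NNNVRYAC", spacer_length_default=22),
    NucleaseProfile("SaCas9", "NNGRRT"),
    NucleaseProfile("SaCas9-KKH", "NNNRRT"),
    NucleaseProfile("AsCpf1", "TTTV", pam_side=PamSide.FIVE_PRIME, spacer_length_default=23),
    NucleaseProfile("LbCpf1", "TTTV", pam_side=PamSide.FIVE_PRIME, spacer_length_default=23),
)

# ABE's window is not standardised; default to BE3's span and expect users
# to override it explicitly when their deaminase differs.
_EDITORS: tuple[EditorPreset, ...] = (
    EditorPreset("BE3", "C", frozenset("AGT"), 13, 17),
    EditorPreset("Target-AID", "C", frozenset("AGT"), 15, 19),
    EditorPreset("ABE", "A", frozenset("G"), 13, 17),
)


def builtin_profiles() -> list[NucleaseProfile]:
    """The 12 built-in nuclease profiles (10 Cas9-family + 2 Cpf1)."""
    return list(_PROFILES)


def builtin_editors() -> list[EditorPreset]:
    """The built-in base-editor presets: BE3, Target-AID, ABE."""
    return list(_EDITORS)


def get_profile(name: str) -> NucleaseProfile:
    """Look up a nuclease profile by name; raise ``KeyError`` listing valid names."""
    for p in _PROFILES:
        if p.name == name:
            return p
    raise KeyError(
        f"unknown nuclease {name!r}; valid names: {', '.join(p.name for p in _PROFILES)}"
    )


def get_editor(name: str) -> EditorPreset:
    """Look up an editor preset by name; raise ``KeyError`` listing valid names."""
    for e in _EDITORS:
        if e.name == name:
            return e
    raise KeyError(
        f"unknown editor {name!r}; valid names: {', '.join(e.name for e in _EDITORS)}"
    )


def registry_json() -> str:
    """The registry as a static JSON document (for ``--list-*`` CLI output)."""
    doc = {
        "nucleases": [
            {**asdict(p), "pam_side": p.pam_side.value} for p in _PROFILES
        ],
        "editors": [
            {
                "name": e.name,
                "edited_base": e.edited_base,
                "product_bases": sorted(e.product_bases),
                "window_proximal": e.window_proximal,
                "window_distal": e.window_distal,
            }
            for e in _EDITORS
        ],
    }
    return json.dumps(doc, indent=2)
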