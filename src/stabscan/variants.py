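"""Parse, format and enumerate missense and single-residue-deletion variants.

Variant labels follow the short protein notation used in the clinical
genetics literature: ``R362C`` for a substitution, and ``ΔK508`` /
``delK508`` / ``K508del`` for an in-frame single-residue deletion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .structure_io import STANDARD_AA, Structure, StructureError

DELTA = "Δ"


class VariantKind(str, Enum):
    MISSENSE = "missense"
    DELETION = "deletion"


class VariantParseError(ValueError):
    """Raised for unparsable or ambiguous variant labels."""


@dataclass(frozen=True, order=True)
class Variant:
    position: int
    kind: VariantKind = field(compare=True)
    wt_aa: str = "X"
    alt_aa: str | None = None

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise VariantParseError(f"position must be positive, got {self.position}")
        if self.wt_aa not in STANDARD_AA:
            raise VariantParseError(f"unknown wild-type amino acid {self.wt_aa!r}")
        if self.kind is VariantKind.MISSENSE:
            if self.alt_aa is None:
                raise VariantParseError("missense variant requires alt_aa")
            if self.alt_aa not in STANDARD_AA:
                raise VariantParseError(f"unknown alternate amino acid {self.alt_aa!r}")
        elif self.alt_aa is not None:
            raise VariantParseError("deletion variant must not carry alt_aa")

    @property
    def is_identity(self) -> bool:
        return self.kind is VariantKind.MISSENSE and self.alt_aa == self.wt_aa

    def __str__(self) -> str:
        return format_variant(self)


_MISSENSE_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")
_DEL_PREFIX_RE = re.compile(rf"^(?:{DELTA}|[Dd][Ee][Ll])([A-Za-z])(\d+)$")
_DEL_SUFFIX_RE = re.compile(r"^([A-Za-z])(\d+)[Dd][Ee][Ll]$")


def parse_variant(label: str) -> Variant:
    """Parse a short variant label ("R362C", "ΔK508", "delK508", "K508del")."""
    if not label or not label.strip():
        raise VariantParseError("empty variant label")
    label = label.strip()
    m = _DEL_PREFIX_RE.match(label) or _DEL_SUFFIX_RE.match(label)
    if m:
        wt, pos = m.group(1).upper(), int(m.group(2))
        return Variant(position=pos, kind=VariantKind.DELETION, wt_aa=wt)
    m = _MISSENSE_RE.match(label)
    if m:
        wt, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        return Variant(position=pos, kind=VariantKind.MISSENSE, wt_aa=wt, alt_aa=alt)
    raise VariantParseError(f"cannot parse variant label {label!r}")


def format_variant(v: Variant, ascii_del: bool = False) -> str:
    """Render a Variant; deletions as "ΔK508" (or "delK508" if ascii_del)."""
    if v.kind is VariantKind.DELETION:
        prefix = "del" if ascii_del else DELTA
        return f"{prefix}{v.wt_aa}{v.position}"
    return f"{v.wt_aa}{v.position}{v.alt_aa}"


def validate_against_structure(v: Variant, s: Structure, chain: str | None = None) -> None:
    """Check that the wild-type letter matches the structure at v.position."""
    res = s.find(v.position, chain)
    if res is None:
        raise StructureError(f"position {v.position} not present in structure")
    if res.key.aa != v.wt_aa:
        raise StructureError(
            f"wild-type mismatch at position {v.position}: variant says "
            f"{v.wt_aa!r}, structure has {res.key.aa!r}")


AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class VariantSet:
    variants: list[Variant]
    domain_start: int
    domain_end: int
    skipped_positions: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.variants)


def enumerate_saturation(s: Structure) -> VariantSet:
    """All 20 substitution identities plus the deletion at every resolved position.

    Per position the order is: substitutions by alphabetical alternate
    letter (the wild-type identity entry included as the reference), then
    the deletion.  Positions flagged as unresolved (missing backbone) are
    skipped and listed in ``skipped_positions``.
    """
    resolved = s.resolved()
    if not resolved:
        raise StructureError("structure has no resolved residues")
    skipped = [r.key.seq_number for r in s.residues if not r.has_backbone()]
    out: list[Variant] = []
    for res in resolved:
        pos, wt = res.key.seq_number, res.key.aa
        for alt in AA_ORDER:
            out.append(Variant(position=pos, kind=VariantKind.MISSENSE, wt_aa=wt, alt_aa=alt))
        out.append(Variant(position=pos, kind=VariantKind.DELETION, wt_aa=wt))
    positions = [r.key.seq_number for r in resolved]
    return VariantSet(variants=out, domain_start=min(positions),
                      domain_end=max(positions), skipped_positions=skipped)
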