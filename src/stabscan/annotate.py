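"""Join ΔΔG records with population-frequency and clinical-label tables.

Provides the fishtail table (allele frequency vs ΔΔG with a derived
stability class), per-segment heatmap matrices, and consensus-motif
scanning over an amino-acid sequence.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .ddg import DdgRecord
from .variants import (Variant, VariantKind, VariantParseError, format_variant,
                       parse_variant)

FREQ_TOLERANCE = 1e-9
DEFAULT_NEUTRAL_MAX = 1.0
DEFAULT_DESTABILIZED_MIN = 3.0

# Consensus patterns for deubiquitylase-docking motifs; 'x' is any residue,
# '[..]' a residue class. Every report states the patterns actually used.
DEFAULT_MOTIFS = {
    "TRAF": "[PA]xxS",
    "UBL12": "KxKxxxK",
}


class ClinicalCategory(str, Enum):
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    VUS = "VUS"
    CONFLICTING = "conflicting"
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"


_CATEGORY_ALIASES = {
    "benign": ClinicalCategory.BENIGN,
    "likely benign": ClinicalCategory.LIKELY_BENIGN,
    "likely_benign": ClinicalCategory.LIKELY_BENIGN,
    "like. benign": ClinicalCategory.LIKELY_BENIGN,
    "vus": ClinicalCategory.VUS,
    "uncertain significance": ClinicalCategory.VUS,
    "conflicting": ClinicalCategory.CONFLICTING,
    "pathogenic": ClinicalCategory.PATHOGENIC,
    "likely pathogenic": ClinicalCategory.LIKELY_PATHOGENIC,
    "likely_pathogenic": ClinicalCategory.LIKELY_PATHOGENIC,
}


class StabilityClass(str, Enum):
    NEUTRAL = "neutral"
    INTERMEDIATE = "intermediate"
    DESTABILIZED = "destabilized"


class AnnotationError(ValueError):
    pass


@dataclass
class AlleleFrequencyRecord:
    variant: Variant
    allele_count: int
    allele_number: int
    frequency: float


@dataclass
class ClinicalLabel:
    variant: Variant
    category: ClinicalCategory


@dataclass
class FishtailRow:
    variant: Variant
    ddg_kcal: float
    frequency: float | None
    category: ClinicalCategory | None
    stability_class: StabilityClass


@dataclass
class FishtailResult:
    rows: list[FishtailRow]
    unmatched_frequency: list[str] = field(default_factory=list)
    unmatched_labels: list[str] = field(default_factory=list)


def classify_stability(ddg_kcal: float,
                       neutral_max: float = DEFAULT_NEUTRAL_MAX,
                       destabilized_min: float = DEFAULT_DESTABILIZED_MIN) -> StabilityClass:
    """Three-way stability class; the destabilized boundary is inclusive."""
    if neutral_max > destabilized_min:
        raise ValueError("neutral_max must be <= destabilized_min")
    if ddg_kcal < neutral_max:
        return StabilityClass.NEUTRAL
    if ddg_kcal >= destabilized_min:
        return StabilityClass.DESTABILIZED
    return StabilityClass.INTERMEDIATE


def _read_tsv(text: str, mandatory: tuple[str, ...]) -> list[dict]:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames is None:
        raise AnnotationError("table has no header row")
    missing = [c for c in mandatory if c not in reader.fieldnames]
    if missing:
        raise AnnotationError(f"missing mandatory column(s): {', '.join(missing)}")
    return list(reader)


def load_frequency_table(tsv: str) -> tuple[list[AlleleFrequencyRecord], list[str]]:
    """Parse a gnomAD-style TSV; malformed rows go to the rejects report."""
    rows = _read_tsv(tsv, ("variant", "allele_count", "allele_number", "frequency"))
    records, rejects = [], []
    for i, row in enumerate(rows, start=2):
        try:
            variant = parse_variant(row["variant"])
            ac = int(row["allele_count"])
            an = int(row["allele_number"])
            freq = float(row["frequency"])
            if ac < 0 or an <= 0 or not 0.0 <= freq <= 1.0:
                raise ValueError("counts/frequency out of range")
            if abs(freq - ac / an) > FREQ_TOLERANCE:
                raise ValueError(f"frequency {freq} inconsistent with {ac}/{an}")
        except (ValueError, VariantParseError, KeyError) as exc:
            rejects.append(f"line {i}: {exc}")
            continue
        records.append(AlleleFrequencyRecord(variant, ac, an, freq))
    return records, rejects


def load_clinical_table(tsv: str) -> list[ClinicalLabel]:
    """Parse a ClinVar-style TSV; unknown category strings are rejected."""
    rows = _read_tsv(tsv, ("variant", "category"))
    out = []
    for i, row in enumerate(rows, start=2):
        raw = row["category"].strip().lower()
        if raw not in _CATEGORY_ALIASES:
            raise AnnotationError(f"line {i}: unknown clinical category {row['category']!r}")
        out.append(ClinicalLabel(parse_variant(row["variant"]), _CATEGORY_ALIASES[raw]))
    return out


def build_fishtail(ddg: list[DdgRecord],
                   freq: list[AlleleFrequencyRecord] | None = None,
                   labels: list[ClinicalLabel] | None = None,
                   neutral_max: float = DEFAULT_NEUTRAL_MAX,
                   destabilized_min: float = DEFAULT_DESTABILIZED_MIN) -> FishtailResult:
    """One row per ΔΔG record, outer-joined with frequency and label tables."""
    freq_map: dict[Variant, AlleleFrequencyRecord] = {}
    for f in freq or []:
        if f.variant in freq_map:
            raise AnnotationError(f"duplicate frequency annotation for {format_variant(f.variant)}")
        freq_map[f.variant] = f
    label_map: dict[Variant, ClinicalLabel] = {}
    for l in labels or []:
        if l.variant in label_map:
            raise AnnotationError(f"duplicate clinical annotation for {format_variant(l.variant)}")
        label_map[l.variant] = l

    seen: set[Variant] = set()
    rows = []
    for rec in ddg:
        v = rec.variant
        seen.add(v)
        f = freq_map.get(v)
        l = label_map.get(v)
        rows.append(FishtailRow(
            variant=v, ddg_kcal=rec.ddg_kcal,
            frequency=f.frequency if f else None,
            category=l.category if l else None,
            stability_class=classify_stability(rec.ddg_kcal, neutral_max, destabilized_min)))
    rows.sort(key=lambda r: (r.variant.position,
                             r.variant.kind is VariantKind.DELETION,
                             r.variant.alt_aa or "~"))
    return FishtailResult(
        rows=rows,
        unmatched_frequency=[format_variant(v) for v in freq_map if v not in seen],
        unmatched_labels=[format_variant(v) for v in label_map if v not in seen])


def fishtail_to_tsv(result: FishtailResult) -> str:
    lines = ["variant\tposition\tddg_kcal\tfrequency\tlog10_frequency\tcategory\tstability_class"]
    for r in result.rows:
        freq = "" if r.frequency is None else f"{r.frequency:.3e}"
        logf = "" if not r.frequency else f"{math.log10(r.frequency):.4f}"
        cat = r.category.value if r.category else ""
        lines.append(f"{format_variant(r.variant)}\t{r.variant.position}\t"
                     f"{r.ddg_kcal:.6f}\t{freq}\t{logf}\t{cat}\t{r.stability_class.value}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Heatmap

HEATMAP_ROWS = ("del",) + tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class HeatmapMatrix:
    positions: list[int]
    rows: tuple[str, ...]
    values: np.ndarray  # shape (21, n_positions); NaN marks missing cells

    def to_tsv(self) -> str:
        lines = ["aa\t" + "\t".join(str(p) for p in self.positions)]
        for label, row in zip(self.rows, self.values):
            cells = ["" if math.isnan(v) else f"{v:.6f}" for v in row]
            lines.append(label + "\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"

    def render(self, path: str) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(self.positions)), 7))
        masked = np.ma.masked_invalid(self.values)
        im = ax.imshow(masked, aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(self.positions)))
        ax.set_xticklabels(self.positions, rotation=90, fontsize=6)
        ax.set_yticks(range(len(self.rows)))
        ax.set_yticklabels(self.rows, fontsize=6)
        fig.colorbar(im, ax=ax, label="ΔΔG (kcal/mol)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def heatmap_matrix(ddg: list[DdgRecord], start: int, end: int) -> HeatmapMatrix:
    """ΔΔG matrix over [start, end], deletion row first."""
    if start > end:
        raise ValueError("start must be <= end")
    positions = list(range(start, end + 1))
    values = np.full((len(HEATMAP_ROWS), len(positions)), np.nan)
    any_record = False
    for rec in ddg:
        pos = rec.variant.position
        if not start <= pos <= end:
            continue
        any_record = True
        row = ("del" if rec.variant.kind is VariantKind.DELETION
               else rec.variant.alt_aa)
        values[HEATMAP_ROWS.index(row), positions.index(pos)] = rec.ddg_kcal
    if not any_record:
        raise AnnotationError(f"no ΔΔG records in range {start}-{end}")
    return HeatmapMatrix(positions=positions, rows=HEATMAP_ROWS, values=values)


# ---------------------------------------------------------------------------
# Consensus-motif scanning

_TOKEN_RE = re.compile(r"\[([A-Z]+)\]|([A-Zx])")


class MotifPatternError(ValueError):
    pass


def compile_motif(pattern: str) -> list[set[str] | None]:
    """Compile a position-wise class pattern ('[PA]xxS') into per-position sets.

    None means "any residue".
    """
    out: list[set[str] | None] = []
    pos = 0
    while pos < len(pattern):
        m = _TOKEN_RE.match(pattern, pos)
        if m is None:
            raise MotifPatternError(f"invalid motif pattern at offset {pos}: {pattern!r}")
        if m.group(1) is not None:
            out.append(set(m.group(1)))
        elif m.group(2) == "x":
            out.append(None)
        else:
            out.append({m.group(2)})
        pos = m.end()
    if not out:
        raise MotifPatternError("empty motif pattern")
    return out


def scan_usp7_motifs(sequence: str,
                     patterns: dict[str, str] | None = None) -> list[tuple[str, int, str]]:
    """All (possibly overlapping) motif matches with 1-based start positions."""
    patterns = DEFAULT_MOTIFS if patterns is None else patterns
    compiled = {name: compile_motif(p) for name, p in patterns.items()}
    sequence = sequence.upper()
    hits = []
    for name, classes in compiled.items():
        k = len(classes)
        for start in range(len(sequence) - k + 1):
            window = sequence[start:start + k]
            if all(cls is None or window[i] in cls for i, cls in enumerate(classes)):
                hits.append((name, start + 1, window))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits
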