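"""Aggregation protocols turning raw scores into variant ΔΔG estimates.

Missense: the variant and the wild type are each scored ``n_iter_missense``
times (independent seeded relax trajectories) and the ΔΔG is the difference
of the two means, divided by ``kcal_divisor`` to reach a kcal/mol scale.

Deletion: an ensemble of ``n_models`` re-closed backbone models is relaxed
in ``n_traj`` independent trajectories each, the median of the resulting
``n_models * n_traj`` scores estimates the variant's raw ΔG, the configured
percentile of the ΔG distribution over all positions is subtracted as the
baseline, and the difference is divided by ``kcal_divisor``.

Sign convention: ΔΔG = E_variant - E_wild-type; positive = destabilizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from ._seeds import derive_seed
from .deletion_modeling import build_deletion_models, relax_ensemble
from .energy import ScorerSpec, make_relax_scorer, substitute_residue
from .structure_io import Structure, StructureError
from .variants import (Variant, VariantKind, enumerate_saturation,
                       format_variant, validate_against_structure)

PERCENTILE_METHODS = {
    "linear_interpolation": "linear",
    "lower": "lower",
    "nearest": "nearest",
}


@dataclass
class ProtocolConfig:
    """Numeric protocol constants; the defaults are the published protocol."""
    n_iter_missense: int = 3
    n_models: int = 25
    n_traj: int = 2
    baseline_percentile: float = 10.0
    kcal_divisor: float = 2.9
    percentile_method: str = "linear_interpolation"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_percentile < 100.0:
            raise ValueError("baseline_percentile must be in (0, 100)")
        if self.kcal_divisor <= 0:
            raise ValueError("kcal_divisor must be positive")
        if self.percentile_method not in PERCENTILE_METHODS:
            raise ValueError(f"unknown percentile method {self.percentile_method!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DdgRecord:
    variant: Variant
    ddg_kcal: float
    raw_stat: float
    raw_scores_wt: list[float] = field(default_factory=list)
    raw_scores_var: list[float] = field(default_factory=list)
    baseline: float | None = None
    scorer: ScorerSpec | None = None
    config: ProtocolConfig | None = None

    @property
    def is_reference(self) -> bool:
        return self.variant.is_identity

    @property
    def n_scores(self) -> int:
        return len(self.raw_scores_var)

    @property
    def label(self) -> str:
        return format_variant(self.variant)


@dataclass
class DeletionScanResult:
    records: list[DdgRecord]
    baseline: float
    dg_distribution: list[float]


def compute_percentile(values, percentile: float, method: str) -> float:
    arr = np.asarray(list(values), dtype=float)
    return float(np.percentile(arr, percentile, method=PERCENTILE_METHODS[method]))


def apply_baseline(dgs: list[float], cfg: ProtocolConfig) -> tuple[float, list[float]]:
    """Subtract the configured percentile baseline and scale to kcal/mol."""
    if len(dgs) < 2:
        raise ValueError("baseline undefined: need at least 2 raw ΔG values")
    baseline = compute_percentile(dgs, cfg.baseline_percentile, cfg.percentile_method)
    return baseline, [(dg - baseline) / cfg.kcal_divisor for dg in dgs]


def missense_ddg(s: Structure, v: Variant, spec: ScorerSpec, cfg: ProtocolConfig,
                 chain: str | None = None, _scorer=None) -> DdgRecord:
    """ΔΔG for a substitution: mean of variant scores minus mean of wild type."""
    if v.kind is not VariantKind.MISSENSE:
        raise ValueError("missense_ddg requires a missense variant")
    validate_against_structure(v, s, chain)
    if v.is_identity:
        return DdgRecord(variant=v, ddg_kcal=0.0, raw_stat=0.0,
                         scorer=spec, config=cfg)
    scorer = _scorer if _scorer is not None else make_relax_scorer(spec)
    label = format_variant(v)
    # wild-type comparator gets the same side-chain reduction as the mutant
    # so the two structures differ only in residue identity
    wt_struct = substitute_residue(s, v.position, v.wt_aa, chain)
    var_struct = substitute_residue(s, v.position, v.alt_aa, chain)
    wt_scores = [scorer(wt_struct, derive_seed(cfg.master_seed, label, "wt", i))
                 for i in range(cfg.n_iter_missense)]
    var_scores = [scorer(var_struct, derive_seed(cfg.master_seed, label, "var", i))
                  for i in range(cfg.n_iter_missense)]
    raw_stat = float(np.mean(var_scores) - np.mean(wt_scores))
    return DdgRecord(variant=v, ddg_kcal=raw_stat / cfg.kcal_divisor,
                     raw_stat=raw_stat, raw_scores_wt=wt_scores,
                     raw_scores_var=var_scores, scorer=spec, config=cfg)


def deletion_raw_dg(s: Structure, v: Variant, spec: ScorerSpec, cfg: ProtocolConfig,
                    _scorer=None, _collect: list | None = None) -> float:
    """Raw ΔG of a deletion: median of n_models × n_traj relaxed-model scores."""
    if v.kind is not VariantKind.DELETION:
        raise ValueError("deletion_raw_dg requires a deletion variant")
    label = format_variant(v, ascii_del=True)
    ensemble = build_deletion_models(
        s, v, cfg.n_models, derive_seed(cfg.master_seed, label, "models"))
    scores = relax_ensemble(ensemble, spec, cfg.n_traj,
                            derive_seed(cfg.master_seed, label, "relax"),
                            _scorer=_scorer)
    if _collect is not None:
        _collect.extend(scores)
    return float(np.median(scores))


def deletion_scan(s: Structure, spec: ScorerSpec, cfg: ProtocolConfig,
                  _scorer=None) -> DeletionScanResult:
    """Deletion ΔΔG for every resolved position of the domain."""
    resolved = s.resolved()
    if len(resolved) < 2:
        raise StructureError(
            "baseline undefined: deletion scan needs at least 2 resolved positions")
    variants = [Variant(position=r.key.seq_number, kind=VariantKind.DELETION,
                        wt_aa=r.key.aa) for r in resolved]
    dgs: list[float] = []
    raw_scores: list[list[float]] = []
    for v in variants:
        collect: list[float] = []
        dgs.append(deletion_raw_dg(s, v, spec, cfg, _scorer=_scorer, _collect=collect))
        raw_scores.append(collect)
    baseline, ddgs = apply_baseline(dgs, cfg)
    records = [DdgRecord(variant=v, ddg_kcal=ddg, raw_stat=dg,
                         raw_scores_var=scores, baseline=baseline,
                         scorer=spec, config=cfg)
               for v, dg, ddg, scores in zip(variants, dgs, ddgs, raw_scores)]
    return DeletionScanResult(records=records, baseline=baseline, dg_distribution=dgs)


def saturation_scan(s: Structure, spec: ScorerSpec, cfg: ProtocolConfig,
                    _scorer=None) -> list[DdgRecord]:
    """All substitutions plus all deletions; deterministic under master_seed."""
    vset = enumerate_saturation(s)
    missense = [v for v in vset.variants if v.kind is VariantKind.MISSENSE]
    records = [missense_ddg(s, v, spec, cfg, _scorer=_scorer) for v in missense]
    deletions = deletion_scan(s, spec, cfg, _scorer=_scorer)
    records.extend(deletions.records)
    records.sort(key=lambda r: (r.variant.position,
                                r.variant.kind is VariantKind.DELETION,
                                r.variant.alt_aa or "~"))
    return records


TSV_COLUMNS = ("position", "wt_aa", "variant", "ddg_kcal", "backend",
               "n_scores", "baseline", "master_seed")


def records_to_tsv(records: list[DdgRecord]) -> str:
    """Serialise scan records to the saturation-table TSV schema."""
    lines = ["\t".join(TSV_COLUMNS)]
    for r in records:
        alt = "del" if r.variant.kind is VariantKind.DELETION else r.variant.alt_aa
        baseline = "" if r.baseline is None else f"{r.baseline:.6f}"
        backend = r.scorer.backend if r.scorer else ""
        seed = r.config.master_seed if r.config else ""
        lines.append(f"{r.variant.position}\t{r.variant.wt_aa}\t{alt}\t"
                     f"{r.ddg_kcal:.6f}\t{backend}\t{r.n_scores}\t{baseline}\t{seed}")
    return "\n".join(lines) + "\n"
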