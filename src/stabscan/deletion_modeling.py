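"""Build ensembles of single-residue-deletion backbone models.

A deletion model is the template minus one residue, with the backbone
re-closed locally: over a window of ``w`` residues downstream of the
deletion, residue ``i`` inherits a blend of the template coordinates of
positions ``i-1`` and ``i`` with a blend weight tapering across the window
(shifted-sequence threading).  Each model of the ensemble then receives an
independent seeded Gaussian jitter on the window atoms before geometry
validation.  Terminal deletions trim without closure and are flagged.

Author numbering is preserved: the deleted position is vacated, downstream
residues keep their deposited numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .energy import ScorerSpec, make_relax_scorer
from .structure_io import Structure, StructureError
from .variants import Variant, VariantKind, format_variant

DEFAULT_WINDOW = 3          # residues of closure per side of the deletion
# Per-model jitter on window heavy atoms. 0.15 A keeps ensemble diversity
# while staying compatible with the CA_CA_RANGE validation on helical
# templates (larger sigmas reject most models at the 4.05 A closure bonds).
DEFAULT_MODEL_SIGMA = 0.15
CA_CA_RANGE = (2.8, 4.3)    # A, accepted consecutive Calpha spacing
MAX_RETRIES = 20


class ClosureError(StructureError):
    """Backbone closure failed geometry validation after all retries."""


@dataclass
class ModelEnsemble:
    variant: Variant
    models: list[Structure]
    template_id: str
    seed: int
    terminal: bool = False
    retries: int = 0
    window: int = DEFAULT_WINDOW

    def __len__(self) -> int:
        return len(self.models)

    def manifest_tsv(self) -> str:
        """Per-model manifest: variant, model index, seed, validation status."""
        lines = ["variant\tmodel_index\tseed\tterminal\tn_residues\tstatus"]
        label = format_variant(self.variant, ascii_del=True)
        for i, m in enumerate(self.models):
            child = derive_seed(self.seed, label, i)
            lines.append(f"{label}\t{i}\t{child}\t{self.terminal}\t{len(m)}\tok")
        return "\n".join(lines) + "\n"


def _closure_weights(window: int) -> np.ndarray:
    # Symmetric taper: the missing residue's worth of backbone slack is
    # spread uniformly over the 2w+1 virtual bonds of the closure window, so
    # every bond stretches by the same factor (2w+2)/(2w+1).
    k = np.arange(1, window + 1)
    return (window + 1 - k) / (2 * window + 1)


def _blend_residue(res, prev_template, weight: float) -> None:
    """Move ``res`` towards the corresponding atoms of ``prev_template``."""
    prev_by_name = {a.name: a.coords for a in prev_template.atoms}
    kept = []
    for a in res.atoms:
        if a.name not in ("N", "CA", "C", "O", "CB"):
            continue  # window side chains reduced to Cbeta stubs
        if a.name in prev_by_name:
            a.coords = weight * prev_by_name[a.name] + (1.0 - weight) * a.coords
        kept.append(a)
    res.atoms = kept


def _validate_window(s: Structure, lo: int, hi: int) -> bool:
    """Check consecutive Calpha spacing across residue indices [lo, hi]."""
    lo = max(lo, 0)
    hi = min(hi, len(s.residues) - 1)
    for i in range(lo, hi):
        a = s.residues[i].atom("CA")
        b = s.residues[i + 1].atom("CA")
        if a is None or b is None:
            return False
        d = float(np.linalg.norm(a.coords - b.coords))
        if not CA_CA_RANGE[0] <= d <= CA_CA_RANGE[1]:
            return False
    return True


def build_deletion_models(s: Structure, v: Variant, n_models: int, seed: int,
                          window: int = DEFAULT_WINDOW,
                          sigma_model: float = DEFAULT_MODEL_SIGMA) -> ModelEnsemble:
    """Build ``n_models`` re-closed backbone models for a deletion variant."""
    if v.kind is not VariantKind.DELETION:
        raise ValueError("build_deletion_models requires a deletion variant")
    idx = next((i for i, r in enumerate(s.residues)
                if r.key.seq_number == v.position and r.has_backbone()), None)
    if idx is None:
        raise StructureError(f"deletion position {v.position} unresolved or absent")
    if s.residues[idx].key.aa != v.wt_aa:
        raise StructureError(
            f"wild-type mismatch at {v.position}: variant {v.wt_aa!r}, "
            f"structure {s.residues[idx].key.aa!r}")

    label = format_variant(v, ascii_del=True)
    terminal = idx == 0 or idx == len(s.residues) - 1
    weights = _closure_weights(window)
    models: list[Structure] = []
    total_retries = 0

    for m in range(n_models):
        if terminal:
            model = s.copy()
            del model.residues[idx]
            models.append(model)
            continue
        ok = False
        for attempt in range(MAX_RETRIES):
            model = s.copy()
            template = s.copy()  # pristine coordinates for blending
            del model.residues[idx]
            # both flanks lean into the vacated position with tapering weight:
            # downstream residue idx+k blends towards template idx+k-1,
            # upstream residue idx-k towards template idx-k+1
            for k in range(1, window + 1):
                down = idx + k
                if down < len(template.residues):
                    _blend_residue(model.residues[down - 1],
                                   template.residues[down - 1], float(weights[k - 1]))
                up = idx - k
                if up >= 0:
                    _blend_residue(model.residues[up],
                                   template.residues[up + 1], float(weights[k - 1]))
            rng = np.random.default_rng(derive_seed(seed, label, m, "jitter", attempt))
            lo, hi = idx - window, idx + window
            for r in model.residues[max(lo, 0):hi]:
                for a in r.atoms:
                    a.coords = a.coords + rng.normal(0.0, sigma_model, 3)
            if _validate_window(model, lo - 1, hi):
                models.append(model)
                total_retries += attempt
                ok = True
                break
        if not ok:
            raise ClosureError(
                f"closure at position {v.position} failed geometry validation "
                f"after {MAX_RETRIES} retries")

    return ModelEnsemble(variant=v, models=models, template_id=s.source_id,
                         seed=seed, terminal=terminal, retries=total_retries,
                         window=window)


def relax_ensemble(e: ModelEnsemble, spec: ScorerSpec, n_traj: int, seed: int,
                   _scorer=None) -> list[float]:
    """Relax every model in ``n_traj`` independent trajectories.

    Returns exactly ``len(e.models) * n_traj`` scores ordered by
    (model index, trajectory index); each trajectory uses a distinct child
    seed derived from ``seed``, the variant label and the two indices.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    scorer = _scorer if _scorer is not None else make_relax_scorer(spec)
    label = format_variant(e.variant, ascii_del=True)
    scores: list[float] = []
    for mi, model in enumerate(e.models):
        for ti in range(n_traj):
            scores.append(scorer(model, derive_seed(seed, label, mi, ti)))
    return scores
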