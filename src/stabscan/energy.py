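"""Pluggable structure scoring.

Two backends satisfy one contract:

* ``builtin`` — a deterministic coarse-grained scorer (clash + burial
  mismatch + backbone strain + volume mismatch) cheap enough for desk-scale
  protocol testing.  Its functional form and constants are artifact-defined
  stand-ins; it is versioned and is NOT expected to reproduce any external
  all-atom force field's numbers.
* ``external`` — an adapter that invokes an external all-atom relax/score
  tool with a configured command template and parses its score table.  If no
  binary is configured the adapter raises a declared-unavailable error; it
  never silently falls back to the builtin scorer.

``relax`` is seeded stochastic perturbation followed by greedy coordinate
descent; it is deterministic for a fixed seed and never returns a score
above that of the input structure.
"""

from __future__ import annotations

import os
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Structure, StructureError, write_pdb

SCORER_VERSION = "builtin-cg-1.0"

# Kyte-Doolittle hydropathy.
HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Mean side-chain volumes (A^3), Zamyatnin-style residue volumes minus the
# glycine backbone contribution; only relative differences matter here.
SIDECHAIN_VOLUME = {
    "G": 0.0, "A": 28.5, "S": 28.9, "C": 48.4, "D": 50.7,
    "P": 52.4, "N": 57.6, "T": 55.8, "E": 78.3, "V": 79.7,
    "Q": 83.4, "H": 93.0, "M": 102.3, "I": 106.4, "L": 106.4,
    "K": 108.5, "R": 113.2, "F": 129.5, "Y": 133.4, "W": 167.3,
}

DEFAULT_PARAMS = {
    "r_clash": 2.8,          # A, non-bonded heavy-atom clash onset
    "k_clash": 10.0,
    "contact_cutoff": 7.0,   # A, Cbeta-Cbeta contact definition
    "w_clash": 1.0,
    "w_burial": 1.0,
    "w_strain": 1.0,
    "w_volume": 1.0,
    "k_strain_len": 5.0,
    "k_strain_ang": 5.0,
    "ideal_ca_ca": 3.8,      # A, virtual Calpha-Calpha bond
    "min_ca_angle_deg": 80.0,  # angles tighter than this are penalised
    "exposure_max": 8.0,     # contacts at/above this count as fully buried
    "expected_exposure_offset": 4.0,
    "expected_exposure_slope": 0.4,
    "buried_min_contacts": 5,
    "k_volume": 0.002,
    # relax knobs
    "jitter_sigma": 0.05,    # A, initial all-atom jitter
    "step_sigma": 0.10,      # A, per-proposal atom displacement
    "max_steps": 40,
    "tol": 1e-4,
}


class ScorerUnavailableError(RuntimeError):
    """External backend requested but no binary is configured/usable."""


class ExternalToolError(RuntimeError):
    """External tool failed; carries the tool's stderr."""


@dataclass
class ScoreBreakdown:
    clash: float
    burial_mismatch: float
    backbone_strain: float
    volume_mismatch: float

    def __post_init__(self) -> None:
        for name in ("clash", "backbone_strain", "volume_mismatch"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be >= 0")
        if not all(np.isfinite([self.clash, self.burial_mismatch,
                                self.backbone_strain, self.volume_mismatch])):
            raise ValueError("non-finite score term")

    @property
    def total(self) -> float:
        return self.clash + self.burial_mismatch + self.backbone_strain + self.volume_mismatch

    @classmethod
    def total_only(cls, total: float) -> "ScoreBreakdown":
        return cls(clash=0.0, burial_mismatch=total, backbone_strain=0.0, volume_mismatch=0.0)


@dataclass
class ScorerSpec:
    backend: str = "builtin"  # builtin | external
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    version_tag: str = SCORER_VERSION

    def __post_init__(self) -> None:
        if self.backend not in ("builtin", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend == "builtin":
            merged = dict(DEFAULT_PARAMS)
            merged.update(self.params)
            self.params = merged

    def p(self, key: str):
        return self.params[key]


def _arrays(s: Structure):
    """Flatten a Structure into numpy arrays for vectorised scoring."""
    coords, res_idx = [], []
    ca, cb, aas, tvol = [], [], [], []
    for i, res in enumerate(s.residues):
        if not res.has_backbone():
            raise StructureError(f"unresolved backbone at {res.key}")
        for a in res.atoms:
            coords.append(a.coords)
            res_idx.append(i)
        ca.append(res.atom("CA").coords)
        cb_atom = res.atom("CB")
        cb.append(cb_atom.coords if cb_atom is not None else res.atom("CA").coords)
        aas.append(res.key.aa)
        tvol.append(res.template_volume if res.template_volume is not None
                    else SIDECHAIN_VOLUME[res.key.aa])
    return (np.asarray(coords), np.asarray(res_idx), np.asarray(ca),
            np.asarray(cb), aas, np.asarray(tvol))


def _contact_counts(cb: np.ndarray, cutoff: float) -> np.ndarray:
    d = np.linalg.norm(cb[:, None, :] - cb[None, :, :], axis=-1)
    n = len(cb)
    idx = np.arange(n)
    near_chain = np.abs(idx[:, None] - idx[None, :]) < 2
    return ((d < cutoff) & ~near_chain).sum(axis=1)


def score(s: Structure, spec: ScorerSpec) -> ScoreBreakdown:
    """Deterministic coarse-grained energy of a validated Structure."""
    if spec.backend != "builtin":
        raise ValueError("score() computes the builtin potential; use external_adapter for external backends")
    p = spec.params
    coords, res_idx, ca, cb, aas, tvol = _arrays(s)

    # clash: non-bonded heavy-atom pairs closer than r_clash
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    nonbonded = np.abs(res_idx[:, None] - res_idx[None, :]) >= 2
    upper = np.triu(np.ones_like(d, dtype=bool), k=1)
    mask = nonbonded & upper & (d < p["r_clash"])
    clash = p["k_clash"] * float(np.sum((p["r_clash"] - d[mask]) ** 2))

    # burial mismatch: hydrophobicity-weighted deviation of exposure from
    # the residue-type expectation, exposure proxied by Cbeta contact count
    contacts = _contact_counts(cb, p["contact_cutoff"])
    exposure = np.clip(p["exposure_max"] - contacts, 0.0, None)
    kd = np.array([HYDROPHOBICITY[a] for a in aas])
    expected = p["expected_exposure_offset"] - p["expected_exposure_slope"] * kd
    burial = float(np.sum(kd * (exposure - expected)))

    # backbone strain: virtual Calpha-Calpha bond length deviation plus a
    # penalty for overly tight Calpha pseudo-angles
    strain = 0.0
    if len(ca) >= 2:
        dd = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        strain += p["k_strain_len"] * float(np.sum((dd - p["ideal_ca_ca"]) ** 2))
    if len(ca) >= 3:
        v1 = ca[:-2] - ca[1:-1]
        v2 = ca[2:] - ca[1:-1]
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        lim = np.cos(np.deg2rad(p["min_ca_angle_deg"]))
        strain += p["k_strain_ang"] * float(np.sum(np.clip(cosang - lim, 0.0, None) ** 2))

    # volume mismatch: buried positions whose side-chain volume deviates
    # from the template position's cavity volume
    vol = np.array([SIDECHAIN_VOLUME[a] for a in aas])
    buried = contacts >= p["buried_min_contacts"]
    volume = p["k_volume"] * float(np.sum((vol[buried] - tvol[buried]) ** 2))

    return ScoreBreakdown(
        clash=p["w_clash"] * clash,
        burial_mismatch=p["w_burial"] * burial,
        backbone_strain=p["w_strain"] * strain,
        volume_mismatch=p["w_volume"] * volume,
    )


def substitute_residue(s: Structure, position: int, new_aa: str,
                       chain: str | None = None) -> Structure:
    """Return a copy with the residue identity at ``position`` changed.

    The side chain is reduced to a Cbeta stub (coarse-grained backend) and
    ``template_volume`` is set to the original residue's side-chain volume
    so the volume-mismatch term sees the cavity left behind.
    """
    out = s.copy()
    res = out.find(position, chain)
    if res is None:
        raise StructureError(f"position {position} not present in structure")
    from .structure_io import ResidueKey  # local import to avoid cycle noise
    old_aa = res.key.aa
    res.key = ResidueKey(res.key.chain_id, res.key.seq_number,
                         res.key.insertion_code, new_aa)
    res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
    res.template_volume = SIDECHAIN_VOLUME[old_aa]
    return out


def relax(s: Structure, spec: ScorerSpec, seed: int) -> tuple[Structure, ScoreBreakdown]:
    """Seeded jitter + greedy coordinate descent on the builtin score.

    Deterministic for a fixed seed.  The returned score is never above the
    score of the input structure: if the perturbed trajectory fails to beat
    the input, the input itself is returned.
    """
    p = spec.params
    base = score(s, spec)
    rng = np.random.default_rng(seed)

    work = s.copy()
    atoms = [a for res in work.residues for a in res.atoms]
    for a in atoms:
        a.coords = a.coords + rng.normal(0.0, p["jitter_sigma"], 3)
    current = score(work, spec)

    n_atoms = len(atoms)
    patience = max(10, n_atoms // 4)
    last_improved = 0
    for step in range(int(p["max_steps"])):
        i = int(rng.integers(n_atoms))
        old = atoms[i].coords.copy()
        delta = rng.normal(0.0, p["step_sigma"], 3)
        accepted = False
        for d in (delta, -delta):  # cheap line probe in both directions
            atoms[i].coords = old + d
            if not np.all(np.isfinite(atoms[i].coords)):
                raise StructureError("non-finite coordinates during descent")
            trial = score(work, spec)
            if trial.total < current.total - p["tol"] * max(1.0, abs(current.total)):
                current = trial
                accepted = True
                last_improved = step
                break
        if not accepted:
            atoms[i].coords = old
            if step - last_improved > patience:
                break

    if current.total <= base.total:
        return work, current
    return s.copy(), base


# ---------------------------------------------------------------------------
# External all-atom backend adapter


def parse_score_table(text: str, total_column: str = "total_score") -> list[ScoreBreakdown]:
    """Parse a whitespace-delimited score table emitted by the external tool.

    Accepts both plain header/row tables and 'SCORE:'-prefixed rows; only the
    total is populated in the returned breakdowns.
    """
    rows = []
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("SCORE:"):
            line = line[len("SCORE:"):].strip()
        fields = line.split()
        if header is None:
            if total_column in fields:
                header = fields
            continue
        if len(fields) != len(header):
            continue
        try:
            rows.append(float(fields[header.index(total_column)]))
        except ValueError:
            continue
    if header is None:
        raise ExternalToolError(f"no header containing {total_column!r} found in score table")
    if not rows:
        raise ExternalToolError("score table contains a header but no data rows")
    return [ScoreBreakdown.total_only(t) for t in rows]


def external_adapter(s: Structure, spec: ScorerSpec, mode: str) -> list[ScoreBreakdown]:
    """Invoke the configured external relax/score tool on ``s``.

    ``spec.params`` must provide ``binary`` and a ``command_template`` with
    ``{binary}`` and ``{pdb}`` placeholders (e.g. the external relax
    invocation with its fast-relax, coordinate-constraint and nstruct
    flags).  The template is logged verbatim.  Raises
    :class:`ScorerUnavailableError` when no usable binary is configured —
    never a silent fallback.
    """
    if mode not in ("relax", "mutate_score"):
        raise ValueError(f"unknown adapter mode {mode!r}")
    binary = spec.params.get("binary")
    template = spec.params.get("command_template")
    if not binary or not template:
        raise ScorerUnavailableError(
            "external backend requested but no binary/command_template configured")
    if not (os.path.isfile(binary) and os.access(binary, os.X_OK)):
        raise ScorerUnavailableError(f"external binary not executable: {binary}")

    with tempfile.TemporaryDirectory(prefix="stabscan-ext-") as tmp:
        pdb_path = os.path.join(tmp, "model.pdb")
        with open(pdb_path, "w") as fh:
            fh.write(write_pdb(s))
        extra = {k: v for k, v in spec.params.items()
                 if isinstance(v, (int, float, str))
                 and k not in ("binary", "pdb", "mode", "workdir")}
        cmd = template.format(binary=binary, pdb=pdb_path, mode=mode,
                              workdir=tmp, **extra)
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True, cwd=tmp)
        if proc.returncode != 0:
            raise ExternalToolError(
                f"external tool exited {proc.returncode}; stderr: {proc.stderr.strip()}")
        score_file = spec.params.get("score_file", "score.sc")
        path = os.path.join(tmp, score_file)
        if os.path.isfile(path):
            with open(path) as fh:
                table = fh.read()
        else:
            table = proc.stdout
        return parse_score_table(table, spec.params.get("total_column", "total_score"))


def make_relax_scorer(spec: ScorerSpec):
    """Return ``f(structure, seed) -> float``: one relax trajectory's score."""
    if spec.backend == "builtin":
        def _f(s: Structure, seed: int) -> float:
            return relax(s, spec, seed)[1].total
        return _f
    def _f(s: Structure, seed: int) -> float:
        out = external_adapter(s, spec, mode="relax")
        return min(b.total for b in out)
    return _f
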