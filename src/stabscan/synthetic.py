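"""Synthetic structures and annotation tables with known ground truth.

These generators stand in for crystallographic input at desk scale: ideal
α-helices built from textbook backbone geometry, a packed two-helix bundle
with geometrically defined buried/exposed/linker position classes, and
variant annotation tables with a planted fishtail structure (common
near-neutral variants vs rare destabilized pathogenic ones).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import ClinicalCategory
from .ddg import DdgRecord
from .structure_io import AtomRecord, Residue, ResidueKey, Structure
from .variants import Variant, VariantKind, format_variant

# Ideal backbone internal coordinates
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.1
ANGLE_N_CA_CB = 110.4
HELIX_PHI = -57.0
HELIX_PSI = -47.0
OMEGA = 180.0

HYDROPHOBIC_CYCLE = "LIVF"
POLAR_CYCLE = "SEKQ"


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from reference atoms A-B-C (natural extension reference frame)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(angle),
                        bond * np.sin(angle) * np.cos(dihedral),
                        bond * np.sin(angle) * np.sin(dihedral)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone_trace(n: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """N/CA/C coordinates for an n-residue chain at fixed (phi, psi)."""
    coords: list[dict[str, np.ndarray]] = []
    ang = np.deg2rad(ANGLE_N_CA_C)
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n):
        prev = coords[-1]
        ni = _nerf(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi)
        cai = _nerf(prev["CA"], prev["C"], ni, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        ci = _nerf(prev["C"], ni, cai, BOND_CA_C, ANGLE_N_CA_C, phi)
        coords.append({"N": ni, "CA": cai, "C": ci})
    return coords


def _decorate(trace: list[dict[str, np.ndarray]], psi: float) -> None:
    """Add carbonyl O and a Cbeta stub to every residue of a backbone trace."""
    for i, res in enumerate(trace):
        res["O"] = _nerf(res["N"], res["CA"], res["C"], BOND_C_O,
                         ANGLE_CA_C_O, psi + 180.0)
        res["CB"] = _nerf(res["C"], res["N"], res["CA"], BOND_CA_CB,
                          ANGLE_N_CA_CB, 122.6)


def _to_structure(trace, sequence: str, chain: str = "A", start: int = 1,
                  source_id: str = "synthetic") -> Structure:
    residues = []
    for i, (res, aa) in enumerate(zip(trace, sequence)):
        atoms = [AtomRecord("N", "N", res["N"]), AtomRecord("CA", "C", res["CA"]),
                 AtomRecord("C", "C", res["C"])]
        if "O" in res:
            atoms.append(AtomRecord("O", "O", res["O"]))
        if "CB" in res and aa != "G":
            atoms.append(AtomRecord("CB", "C", res["CB"]))
        residues.append(Residue(key=ResidueKey(chain, start + i, "", aa), atoms=atoms))
    return Structure(residues=residues, source_id=source_id)


def make_ideal_helix(n: int, sequence: str | None = None, chain: str = "A",
                     start: int = 1) -> Structure:
    """Ideal α-helix (φ = −57°, ψ = −47°) with Cβ stubs.

    Deterministic; consecutive Cα-Cα spacing ≈ 3.8 Å, rise ≈ 1.5 Å/residue.
    """
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    if sequence is None:
        sequence = ("AELKAQIDALEKQNAELKAQIDAL" * (n // 24 + 1))[:n]
    if len(sequence) != n:
        raise ValueError(f"sequence length {len(sequence)} != n {n}")
    trace = _backbone_trace(n, HELIX_PHI, HELIX_PSI)
    _decorate(trace, HELIX_PSI)
    return _to_structure(trace, sequence, chain=chain, start=start,
                         source_id="synthetic-helix")


@dataclass
class SyntheticStructureSpec:
    topology: str = "two_helix_bundle"  # single_helix | helix_linker_helix | two_helix_bundle
    helix_length: int = 12
    linker_length: int = 4
    interaxis_distance: float = 10.0
    sequence: str = "auto"
    seed: int = 0
    chain: str = "A"
    start: int = 1


def _helix_frame(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(axis unit vector, centroid) of a helix from its Cα coordinates."""
    ca = np.array([r.atom("CA").coords for r in s.residues])
    centroid = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return axis, centroid


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # pick any perpendicular axis for a 180-degree flip
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2.0 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _transform(s: Structure, rot: np.ndarray, shift: np.ndarray) -> None:
    for res in s.residues:
        for a in res.atoms:
            a.coords = rot @ a.coords + shift


def _canonicalize(h: Structure) -> None:
    """Rotate/translate so the helix axis is +z through the xy origin with
    the first Cα at z = 0."""
    axis, _ = _helix_frame(h)
    rot = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    _transform(h, rot, np.zeros(3))
    ca = np.array([r.atom("CA").coords for r in h.residues])
    centroid = ca.mean(axis=0)
    shift = np.array([-centroid[0], -centroid[1], -h.residues[0].atom("CA").coords[2]])
    _transform(h, np.eye(3), shift)


def _rotate_z_to_phase(h: Structure, ca_coords: np.ndarray, target_phase: float) -> None:
    """Rotate about the z axis so ``ca_coords`` lands at ``target_phase``."""
    phase = float(np.arctan2(ca_coords[1], ca_coords[0]))
    a = target_phase - phase
    rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                    [np.sin(a), np.cos(a), 0.0],
                    [0.0, 0.0, 1.0]])
    _transform(h, rot, np.zeros(3))


def make_two_helix_bundle(spec: SyntheticStructureSpec) -> tuple[Structure, dict[int, str]]:
    """Antiparallel two-helix bundle joined by a turn linker.

    Returns the structure plus geometric ground-truth classes per author
    position: 'buried' (Cβ faces the partner helix), 'exposed', or 'linker'.
    The ground truth is purely geometric — independent of any scorer.
    """
    n, nl, dist = spec.helix_length, spec.linker_length, spec.interaxis_distance
    if n < 4 or nl < 1:
        raise ValueError("need helix_length >= 4 and linker_length >= 1")

    h1 = make_ideal_helix(n, "A" * n)
    _canonicalize(h1)
    # orient the junction residue towards +y so the linker arc length is
    # controlled by the inter-axis distance alone
    _rotate_z_to_phase(h1, h1.residues[-1].atom("CA").coords, np.pi / 2)

    h2 = make_ideal_helix(n, "A" * n)
    _canonicalize(h2)
    flip = np.diag([1.0, -1.0, -1.0])  # 180 degrees about x: axis becomes -z
    _transform(h2, flip, np.zeros(3))
    _rotate_z_to_phase(h2, h2.residues[0].atom("CA").coords, np.pi / 2)
    ztop = h1.residues[-1].atom("CA").coords[2]
    _transform(h2, np.eye(3), np.array([dist, 0.0, ztop]))

    # packing sanity: the two helices must not interpenetrate
    a1 = np.array([a.coords for r in h1.residues for a in r.atoms])
    a2 = np.array([a.coords for r in h2.residues for a in r.atoms])
    dmin = float(np.linalg.norm(a1[:, None, :] - a2[None, :, :], axis=-1).min())
    if dmin < 2.8:
        raise ValueError(
            f"inter-axis distance {dist} A causes steric clashes (min dist {dmin:.2f} A)")

    # linker: circular arc over the top from helix1 end to helix2 start
    p0 = h1.residues[-1].atom("CA").coords
    p1 = h2.residues[0].atom("CA").coords
    mid = 0.5 * (p0 + p1)
    u = p1 - p0
    radius = 0.5 * float(np.linalg.norm(u))
    u /= np.linalg.norm(u)
    w = np.array([0.0, 0.0, 1.0])
    linker_ca = []
    for k in range(1, nl + 1):
        t = np.pi * k / (nl + 1)
        linker_ca.append(mid - radius * np.cos(t) * u + radius * np.sin(t) * w)
    spacing = 2.0 * radius * np.sin(np.pi / (2 * (nl + 1)))
    if not 2.8 <= spacing <= 4.3:
        raise ValueError(
            f"linker Cα spacing {spacing:.2f} A outside [2.8, 4.3]; "
            f"adjust linker_length or interaxis_distance")

    # assemble residues; linker backbone is approximated around the CA trace
    residues: list[Residue] = []
    classes: dict[int, str] = {}
    pos = spec.start
    other_dir = {0: np.array([1.0, 0.0, 0.0]), 1: np.array([-1.0, 0.0, 0.0])}
    hydro = polar = 0
    for hi, helix in enumerate((h1, h2)):
        if hi == 1:
            # linker residues between the helices
            for j, ca in enumerate(linker_ca):
                prev_ca = linker_ca[j - 1] if j > 0 else p0
                next_ca = linker_ca[j + 1] if j + 1 < len(linker_ca) else p1
                u_prev = (prev_ca - ca) / np.linalg.norm(prev_ca - ca)
                u_next = (next_ca - ca) / np.linalg.norm(next_ca - ca)
                atoms = [AtomRecord("N", "N", ca + BOND_N_CA * u_prev),
                         AtomRecord("CA", "C", ca),
                         AtomRecord("C", "C", ca + BOND_CA_C * u_next)]
                residues.append(Residue(key=ResidueKey(spec.chain, pos, "", "G"),
                                        atoms=atoms))
                classes[pos] = "linker"
                pos += 1
        for ri, res in enumerate(helix.residues):
            ca = res.atom("CA").coords
            cb = res.atom("CB").coords
            # buried = side chain faces the partner helix AND the position is
            # not in the frayed terminal turn (helix ends are solvent-exposed)
            inward = float(np.dot(cb - ca, other_dir[hi])) > 0.5
            interior = 2 <= ri < n - 2
            buried = inward and interior
            if spec.sequence == "auto":
                if buried:
                    aa = HYDROPHOBIC_CYCLE[hydro % len(HYDROPHOBIC_CYCLE)]
                    hydro += 1
                else:
                    aa = POLAR_CYCLE[polar % len(POLAR_CYCLE)]
                    polar += 1
            else:
                aa = spec.sequence[pos - spec.start]
            residues.append(Residue(key=ResidueKey(spec.chain, pos, "", aa),
                                    atoms=[AtomRecord(a.name, a.element,
                                                      a.coords.copy())
                                           for a in res.atoms]))
            classes[pos] = "buried" if buried else "exposed"
            pos += 1

    s = Structure(residues=residues, source_id=f"synthetic-{spec.topology}")
    return s, classes


def make_helix_linker_helix(spec: SyntheticStructureSpec | None = None
                            ) -> tuple[Structure, dict[int, str]]:
    """Helix-turn-helix fixture; same geometry as the bundle, named per use."""
    spec = spec or SyntheticStructureSpec(topology="helix_linker_helix")
    return make_two_helix_bundle(spec)


# ---------------------------------------------------------------------------
# Annotation tables with planted fishtail structure


@dataclass
class SyntheticAnnotationSpec:
    n_common: int = 50
    n_rare_pathogenic: int = 20
    common_ddg_mean: float = 0.0
    common_ddg_sd: float = 0.5
    pathogenic_ddg_mean: float = 4.0
    pathogenic_ddg_sd: float = 1.0
    common_freq_range: tuple[float, float] = (1e-3, 1e-1)
    rare_freq_range: tuple[float, float] = (1e-6, 1e-4)
    allele_number: int = 150000
    position_start: int = 341
    seed: int = 0


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(np.log10(lo), np.log10(hi)))


def make_annotation_tables(spec: SyntheticAnnotationSpec) -> tuple[str, str, pd.DataFrame]:
    """(frequency TSV, clinical-label TSV, truth table).

    Common variants draw near-neutral ΔΔG, high frequency and benign labels;
    rare pathogenic variants draw high ΔΔG and low frequency.  The truth
    table records each variant's stratum and generated values for recovery
    tests.  Byte-deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    rows = []
    pos = spec.position_start
    for stratum, count, mu, sd, frange, cats in (
            ("common", spec.n_common, spec.common_ddg_mean, spec.common_ddg_sd,
             spec.common_freq_range,
             (ClinicalCategory.BENIGN, ClinicalCategory.LIKELY_BENIGN)),
            ("rare_pathogenic", spec.n_rare_pathogenic, spec.pathogenic_ddg_mean,
             spec.pathogenic_ddg_sd, spec.rare_freq_range,
             (ClinicalCategory.PATHOGENIC,))):
        for _ in range(count):
            wt = aas[int(rng.integers(len(aas)))]
            alt = aas[int(rng.integers(len(aas)))]
            while alt == wt:
                alt = aas[int(rng.integers(len(aas)))]
            variant = Variant(position=pos, kind=VariantKind.MISSENSE,
                              wt_aa=wt, alt_aa=alt)
            ddg = float(rng.normal(mu, sd))
            freq = _loguniform(rng, *frange)
            ac = max(1, round(freq * spec.allele_number))
            freq = ac / spec.allele_number  # keep count/frequency exactly consistent
            cat = cats[int(rng.integers(len(cats)))]
            rows.append({"variant": format_variant(variant), "stratum": stratum,
                         "ddg_kcal": ddg, "allele_count": ac,
                         "allele_number": spec.allele_number,
                         "frequency": freq, "category": cat.value})
            pos += 1
    truth = pd.DataFrame(rows)

    freq_buf = io.StringIO()
    freq_buf.write("variant\tallele_count\tallele_number\tfrequency\n")
    for r in rows:
        freq_buf.write(f"{r['variant']}\t{r['allele_count']}\t"
                       f"{r['allele_number']}\t{r['frequency']:.12g}\n")
    label_buf = io.StringIO()
    label_buf.write("variant\tcategory\n")
    for r in rows:
        label_buf.write(f"{r['variant']}\t{r['category']}\n")
    return freq_buf.getvalue(), label_buf.getvalue(), truth


def truth_to_ddg_records(truth: pd.DataFrame) -> list[DdgRecord]:
    """Wrap the truth table's generated ΔΔG values as scan records."""
    from .variants import parse_variant
    return [DdgRecord(variant=parse_variant(r["variant"]),
                      ddg_kcal=float(r["ddg_kcal"]),
                      raw_stat=float(r["ddg_kcal"]) * 2.9)
            for _, r in truth.iterrows()]


def ground_truth_json(classes: dict[int, str]) -> str:
    return json.dumps({str(k): v for k, v in sorted(classes.items())}, indent=1)
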