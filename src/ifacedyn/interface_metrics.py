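"""Non-H-bond interface quantities.

Buried solvent-accessible surface area (Shrake–Rupley with deterministic
golden-section sphere points), pairwise interaction energy with a
CHARMM-style switched 12 Å cutoff, partner-aligned segment RMSD via Kabsch
superposition, and water-accessibility counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ifacedyn.structure_io import (
    Frame,
    SelectionSpec,
    Trajectory,
    select_indices,
)

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_K = 332.0636

#: Fallback SASA radii by element (Å) when no parameter table is supplied.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70


class MetricsError(Exception):
    pass


class ParameterError(MetricsError):
    """Atoms lack entries in the parameter table; the message lists them."""


class GeometryError(MetricsError):
    """Superposition input is degenerate (too few or collinear atoms)."""


@dataclass(frozen=True)
class ParamEntry:
    """Per-atom nonbonded parameters (charges, LJ, SASA radius)."""

    chain_id: str
    residue_seq: int
    atom_name: str
    charge: float
    epsilon: float
    rmin_half: float
    radius: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.atom_name)


ParamTable = dict[tuple[str, int, str], ParamEntry]


def read_param_table(path: str | Path) -> ParamTable:
    """Read a whitespace-separated atom-parameter table ('#' comments).

    Columns: chain, residue_seq, atom_name, charge_e, epsilon_kcal_mol,
    rmin_half_A, radius_A.
    """
    table: ParamTable = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ParameterError(
                f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
            )
        try:
            entry = ParamEntry(
                chain_id=parts[0],
                residue_seq=int(parts[1]),
                atom_name=parts[2],
                charge=float(parts[3]),
                epsilon=float(parts[4]),
                rmin_half=float(parts[5]),
                radius=float(parts[6]),
            )
        except ValueError as exc:
            raise ParameterError(f"{path}:{lineno}: {exc}") from exc
        table[entry.key] = entry
    return table


def write_param_table(table: ParamTable, path: str | Path) -> None:
    lines = ["# chain residue_seq atom_name charge_e epsilon_kcal_mol rmin_half_A radius_A"]
    for entry in table.values():
        lines.append(
            f"{entry.chain_id} {entry.residue_seq} {entry.atom_name} "
            f"{entry.charge:.6f} {entry.epsilon:.6f} {entry.rmin_half:.6f} "
            f"{entry.radius:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EnergyBreakdown:
    electrostatic: float
    vdw: float

    @property
    def total(self) -> float:
        return self.electrostatic + self.vdw


@dataclass
class SasaResult:
    per_atom: dict[tuple[str, int, str], float]
    total: float
    probe_radius: float
    n_sphere_points: int


@dataclass
class Transform:
    """Proper rigid transform x → R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _sasa_radii(frame: Frame, idx: np.ndarray, params: ParamTable | None) -> np.ndarray:
    radii = np.empty(idx.size)
    missing = []
    for k, i in enumerate(idx):
        atom = frame.atoms[i]
        if params is not None:
            entry = params.get(atom.key)
            if entry is None:
                missing.append(atom.key)
                continue
            radii[k] = entry.radius
        else:
            radii[k] = DEFAULT_RADII.get(atom.element, DEFAULT_RADIUS)
    if missing:
        raise ParameterError(f"no SASA radius for atoms: {missing[:10]}")
    return radii


def sasa(
    frame: Frame,
    selection: SelectionSpec,
    probe_A: float = 1.4,
    n_points: int = 960,
    params: ParamTable | None = None,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area of a selection.

    Hydrogens are excluded; each heavy atom's surface is sampled on a
    deterministic spiral of ``n_points`` points, and a point is accessible
    when it lies outside every other expanded sphere of the selection.
    """
    heavy = SelectionSpec(selection.ranges, atom_class="heavy", name_patterns=selection.name_patterns)
    idx = select_indices(frame, heavy)
    if idx.size == 0:
        raise MetricsError("sasa: selection resolves to no heavy atoms")
    coords = frame.coords[idx]
    radii = _sasa_radii(frame, idx, params) + probe_A
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    per_atom: dict[tuple[str, int, str], float] = {}
    total = 0.0
    for k in range(idx.size):
        pts = coords[k] + radii[k] * unit
        neighbors = [
            j
            for j in tree.query_ball_point(coords[k], radii[k] + max_r)
            if j != k and np.linalg.norm(coords[j] - coords[k]) < radii[k] + radii[j]
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        frac = accessible.sum() / n_points
        area = 4.0 * np.pi * radii[k] ** 2 * frac
        per_atom[frame.atoms[idx[k]].key] = float(area)
        total += area
    return SasaResult(per_atom, float(total), probe_A, n_points)


def _union_spec(a: SelectionSpec, b: SelectionSpec) -> SelectionSpec:
    if a.atom_class != b.atom_class or a.name_patterns != b.name_patterns:
        raise MetricsError("buried_sasa sides must share atom_class/name_patterns")
    return SelectionSpec(a.ranges + b.ranges, atom_class=a.atom_class, name_patterns=a.name_patterns)


def buried_sasa(
    frame: Frame,
    side_a: SelectionSpec,
    side_b: SelectionSpec,
    probe_A: float = 1.4,
    n_points: int = 960,
    params: ParamTable | None = None,
) -> float:
    """Interface area: SASA(a alone) + SASA(b alone) − SASA(a ∪ b), in Å²."""
    ia = set(select_indices(frame, side_a).tolist())
    ib = set(select_indices(frame, side_b).tolist())
    if ia & ib:
        raise MetricsError("buried_sasa sides overlap")
    s_a = sasa(frame, side_a, probe_A, n_points, params).total
    s_b = sasa(frame, side_b, probe_A, n_points, params).total
    s_ab = sasa(frame, _union_spec(side_a, side_b), probe_A, n_points, params).total
    return s_a + s_b - s_ab


def switching_function(r: np.ndarray, switch_on_A: float, cutoff_A: float) -> np.ndarray:
    """CHARMM-style smooth switching: 1 below r_on, 0 at and beyond cutoff."""
    r = np.asarray(r, dtype=float)
    r2, on2, off2 = r**2, switch_on_A**2, cutoff_A**2
    sw = np.where(
        r2 <= on2,
        1.0,
        np.where(
            r2 >= off2,
            0.0,
            (off2 - r2) ** 2 * (off2 + 2.0 * r2 - 3.0 * on2) / (off2 - on2) ** 3,
        ),
    )
    return sw


def _gather_params(frame: Frame, idx: np.ndarray, params: ParamTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q = np.empty(idx.size)
    eps = np.empty(idx.size)
    rmin_h = np.empty(idx.size)
    missing = []
    for k, i in enumerate(idx):
        entry = params.get(frame.atoms[i].key)
        if entry is None:
            missing.append(frame.atoms[i].key)
            continue
        q[k], eps[k], rmin_h[k] = entry.charge, entry.epsilon, entry.rmin_half
    if missing:
        raise ParameterError(f"no nonbonded parameters for atoms: {missing[:10]}")
    return q, eps, rmin_h


def interaction_energy(
    frame: Frame,
    side_a: SelectionSpec,
    side_b: SelectionSpec,
    params: ParamTable,
    cutoff_A: float = 12.0,
    switch_on_A: float = 10.0,
) -> EnergyBreakdown:
    """Cross-side pairwise Coulomb + Lennard-Jones energy in kcal/mol.

    Both terms are multiplied by the smooth switching function between
    ``switch_on_A`` and ``cutoff_A`` and vanish beyond the cutoff.  LJ
    combination is arithmetic for rmin and geometric for epsilon.
    """
    ia = select_indices(frame, side_a)
    ib = select_indices(frame, side_b)
    if ia.size == 0 or ib.size == 0:
        raise MetricsError("interaction_energy: empty selection")
    if set(ia.tolist()) & set(ib.tolist()):
        raise MetricsError("interaction_energy sides overlap")
    qa, ea, ra = _gather_params(frame, ia, params)
    qb, eb, rb = _gather_params(frame, ib, params)
    xa, xb = frame.coords[ia], frame.coords[ib]

    tree_a, tree_b = cKDTree(xa), cKDTree(xb)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff_A)
    elec = 0.0
    vdw = 0.0
    for i, hits in enumerate(pairs):
        if not hits:
            continue
        j = np.asarray(hits, dtype=int)
        r = np.linalg.norm(xb[j] - xa[i], axis=1)
        keep = (r < cutoff_A) & (r > 1e-9)
        if not keep.any():
            continue
        j, r = j[keep], r[keep]
        sw = switching_function(r, switch_on_A, cutoff_A)
        elec += float(np.sum(COULOMB_K * qa[i] * qb[j] / r * sw))
        eps_ij = np.sqrt(ea[i] * eb[j])
        rmin_ij = ra[i] + rb[j]
        frac6 = (rmin_ij / r) ** 6
        vdw += float(np.sum(eps_ij * (frac6**2 - 2.0 * frac6) * sw))
    return EnergyBreakdown(electrostatic=elec, vdw=vdw)


def superpose_kabsch(
    mobile: Frame,
    reference: Frame,
    fit_selection: SelectionSpec,
) -> Transform:
    """Least-squares optimal proper rigid transform of mobile onto reference.

    Atoms are matched by (chain, residue, atom name); at least 3
    non-collinear fit atoms are required.
    """
    P, Q = _matched_coords(mobile, reference, fit_selection)
    if P.shape[0] < 3:
        raise GeometryError("superposition needs at least 3 matched atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise GeometryError("fit atoms are collinear")
    B = P0.T @ Q0
    U, _, Vt = np.linalg.svd(B)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return Transform(rotation=R, translation=t)


def _matched_coords(
    mobile: Frame, reference: Frame, selection: SelectionSpec
) -> tuple[np.ndarray, np.ndarray]:
    heavy = SelectionSpec(selection.ranges, atom_class="heavy", name_patterns=selection.name_patterns)
    ref_idx = select_indices(reference, heavy)
    mob_map = {
        mobile.atoms[i].key: i for i in select_indices(mobile, heavy)
    }
    ref_keys = [reference.atoms[i].key for i in ref_idx]
    missing = [k for k in ref_keys if k not in mob_map]
    extra = [k for k in mob_map if k not in set(ref_keys)]
    if missing or extra:
        raise MetricsError(
            f"selection resolves differently: missing from mobile {missing[:5]}, "
            f"extra in mobile {extra[:5]}"
        )
    P = np.array([mobile.atoms[mob_map[k]].position for k in ref_keys])
    Q = reference.coords[ref_idx]
    return P, Q


def aligned_segment_rmsd(
    traj: Trajectory,
    reference: Frame,
    fit_selection: SelectionSpec,
    rmsd_selection: SelectionSpec,
) -> np.ndarray:
    """Per-frame heavy-atom RMSD of a segment after fitting on the partner.

    Each frame is superposed onto the reference using ``fit_selection``
    (e.g. the antibody); the RMSD of ``rmsd_selection`` is then measured
    without refitting, so genuine segment motion relative to the partner is
    reported while global rigid motion cancels.
    """
    out = np.empty(len(traj.frames))
    for k, frame in enumerate(traj.frames):
        tf = superpose_kabsch(frame, reference, fit_selection)
        P, Q = _matched_coords(frame, reference, rmsd_selection)
        moved = tf.apply(P)
        out[k] = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return out


def count_waters_within(
    frame: Frame,
    selection: SelectionSpec,
    radius_A: float = 4.0,
) -> int:
    """Distinct water molecules with oxygen within ``radius_A`` (inclusive)
    of any heavy atom of the selection."""
    heavy = SelectionSpec(selection.ranges, atom_class="heavy", name_patterns=selection.name_patterns)
    sel_idx = select_indices(frame, heavy)
    sel_idx = np.array(
        [i for i in sel_idx if not frame.atoms[i].is_water], dtype=int
    )
    if sel_idx.size == 0:
        raise MetricsError("count_waters_within: selection has no heavy atoms")
    wat_idx = select_indices(frame, SelectionSpec(atom_class="water_oxygen"))
    if wat_idx.size == 0:
        return 0
    tree = cKDTree(frame.coords[sel_idx])
    d, _ = tree.query(frame.coords[wat_idx], k=1)
    molecules = {
        (frame.atoms[i].chain_id, frame.atoms[i].residue_seq)
        for i, dist in zip(wat_idx, d)
        if dist <= radius_A
    }
    return len(molecules)
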