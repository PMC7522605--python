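"""Rigid-body scenario construction: segment truncation and hinge rotations.

A scenario variant is built from a native two-partner complex either by
removing a segment outright or by swinging it about a hinge axis so that it
moves away from the binding partner while every other atom stays fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from ifacedyn.structure_io import (
    Frame,
    ResidueRange,
    SelectionSpec,
    select_indices,
)


class BuildError(Exception):
    """Scenario construction failed (degenerate segment, clashes, ...)."""


@dataclass
class RotationPlan:
    """A rotation of one segment about an axis anchored at a hinge Cα."""

    segment: ResidueRange
    hinge_residue: int
    axis_unit: np.ndarray
    pivot: np.ndarray
    angle_deg: float

    def __post_init__(self) -> None:
        self.axis_unit = np.asarray(self.axis_unit, dtype=float)
        self.pivot = np.asarray(self.pivot, dtype=float)
        if abs(np.linalg.norm(self.axis_unit) - 1.0) > 1e-9:
            raise ValueError("axis_unit must have unit norm")
        if not (-360.0 < self.angle_deg <= 360.0):
            raise ValueError("angle_deg must lie in (-360, 360]")

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(
            np.deg2rad(self.angle_deg) * self.axis_unit
        ).as_matrix()


@dataclass
class ClashReport:
    """Closest-approach summary between two disjoint selections."""

    min_distance_A: float
    n_pairs_below_cutoff: int
    offending_pairs: list  # (atom key, atom key, distance)

    @property
    def clash_free(self) -> bool:
        return self.n_pairs_below_cutoff == 0


def truncate_segment(frame: Frame, segment: ResidueRange) -> Frame:
    """Remove every atom of ``segment``; everything else is untouched.

    The new terminal residue adjacent to the cut is recorded in frame
    metadata under ``"capping"`` (cap atoms themselves are out of scope).
    """
    seg_spec = SelectionSpec((segment,))
    seg_idx = set(select_indices(frame, seg_spec).tolist())
    if not seg_idx:
        raise BuildError(f"segment {segment} resolves to no atoms")
    chain_residues = sorted(
        {a.residue_seq for a in frame.atoms if a.chain_id == segment.chain_id}
    )
    removed = sorted(
        {
            frame.atoms[i].residue_seq
            for i in seg_idx
            if frame.atoms[i].chain_id == segment.chain_id
        }
    )
    if set(removed) >= set(chain_residues):
        raise BuildError(
            f"refusing to truncate: segment {segment} covers the whole "
            f"chain {segment.chain_id}"
        )
    kept_atoms = [a for i, a in enumerate(frame.atoms) if i not in seg_idx]
    out = Frame(
        kept_atoms,
        frame_index=frame.frame_index,
        time_ps=frame.time_ps,
        metadata=dict(frame.metadata),
    )
    remaining = [r for r in chain_residues if r not in removed]
    # the retained residue closest to the cut gets capping metadata
    if removed[0] <= remaining[0]:
        new_terminus, terminus_kind = remaining[0], "N"
    else:
        new_terminus, terminus_kind = remaining[-1], "C"
    caps = list(out.metadata.get("capping", []))
    caps.append(
        {
            "chain_id": segment.chain_id,
            "residue_seq": new_terminus,
            "terminus": terminus_kind,
        }
    )
    out.metadata["capping"] = caps
    return out


def _heavy_centroid(frame: Frame, spec: SelectionSpec) -> np.ndarray:
    idx = select_indices(
        frame, SelectionSpec(spec.ranges, atom_class="heavy", name_patterns=spec.name_patterns)
    )
    if idx.size == 0:
        raise BuildError("selection resolves to no heavy atoms")
    return frame.coords[idx].mean(axis=0)


def _fallback_axis(direction: np.ndarray) -> np.ndarray:
    """Unit vector orthogonal to ``direction``, smallest-index convention."""
    u = direction / np.linalg.norm(direction)
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        perp = e - np.dot(e, u) * u
        n = np.linalg.norm(perp)
        if n > 1e-8:
            return perp / n
    raise BuildError("cannot construct a fallback rotation axis")


def find_hinge_residue(frame: Frame, segment: ResidueRange) -> int:
    """Junction residue where the segment meets the retained chain body.

    For a segment at the chain's N-terminal end the hinge is the first
    retained residue after it; for a segment attached at its start the hinge
    is the segment's own first residue.
    """
    chain_residues = sorted(
        {a.residue_seq for a in frame.atoms if a.chain_id == segment.chain_id}
    )
    if not chain_residues:
        raise BuildError(f"chain {segment.chain_id} absent from frame")
    seg_res = [r for r in chain_residues if segment.contains(segment.chain_id, r)]
    if not seg_res:
        raise BuildError(f"segment {segment} resolves to no residues")
    below = [r for r in chain_residues if r < seg_res[0]]
    above = [r for r in chain_residues if r > seg_res[-1]]
    if below:
        return seg_res[0]
    if above:
        return above[0]
    raise BuildError("segment covers the whole chain; no hinge exists")


def plan_rotation(
    frame: Frame,
    segment: ResidueRange,
    partner: SelectionSpec,
    angle_deg: float,
    hinge_residue: int | None = None,
) -> RotationPlan:
    """Plan a hinge rotation that moves the segment away from the partner.

    The pivot is the Cα of the hinge residue; the axis is the normalized
    cross product of (segment centroid − pivot) and (partner centroid −
    pivot); the sign of the angle is chosen so the rotated segment centroid
    moves away from the partner centroid.
    """
    if hinge_residue is None:
        hinge_residue = find_hinge_residue(frame, segment)
    ca = [
        a
        for a in frame.atoms
        if a.chain_id == segment.chain_id
        and a.residue_seq == hinge_residue
        and a.atom_name == "CA"
    ]
    if not ca:
        raise BuildError(
            f"hinge residue {segment.chain_id}:{hinge_residue} has no CA atom"
        )
    pivot = ca[0].position.astype(float)
    seg_centroid = _heavy_centroid(frame, SelectionSpec((segment,)))
    partner_centroid = _heavy_centroid(frame, partner)

    v_seg = seg_centroid - pivot
    v_par = partner_centroid - pivot
    axis = np.cross(v_seg, v_par)
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        warnings.warn(
            "degenerate rotation geometry (collinear centroids); using "
            "fallback axis",
            stacklevel=2,
        )
        axis_unit = _fallback_axis(v_par if np.linalg.norm(v_par) > 1e-8 else np.array([1.0, 0, 0]))
    else:
        axis_unit = axis / norm

    plan = RotationPlan(segment, hinge_residue, axis_unit, pivot, float(angle_deg))
    if abs(angle_deg) < 1e-12:
        return plan
    # pick the sign that increases segment-partner centroid separation
    best = None
    for sign in (+1.0, -1.0):
        cand = RotationPlan(segment, hinge_residue, axis_unit, pivot, sign * abs(float(angle_deg)))
        moved = cand.matrix @ (seg_centroid - pivot) + pivot
        d = np.linalg.norm(moved - partner_centroid)
        if best is None or d > best[0]:
            best = (d, cand)
    d0 = np.linalg.norm(seg_centroid - partner_centroid)
    if best[0] <= d0:
        warnings.warn(
            "rotation does not increase segment-partner separation for "
            "either sign; keeping the larger-distance sign",
            stacklevel=2,
        )
    return best[1]


def rotate_segment(frame: Frame, plan: RotationPlan) -> Frame:
    """Apply ``plan`` rigidly to the segment; every other atom is unchanged."""
    idx = select_indices(frame, SelectionSpec((plan.segment,)))
    if idx.size == 0:
        raise BuildError(f"segment {plan.segment} resolves to no atoms")
    coords = frame.coords.copy()
    R = plan.matrix
    coords[idx] = (coords[idx] - plan.pivot) @ R.T + plan.pivot
    return frame.with_coords(coords)


def clash_check(
    frame: Frame,
    a: SelectionSpec,
    b: SelectionSpec,
    cutoff_A: float = 2.0,
) -> ClashReport:
    """Minimum heavy-atom distance between selections and all pairs < cutoff."""
    a_heavy = SelectionSpec(a.ranges, atom_class="heavy", name_patterns=a.name_patterns)
    b_heavy = SelectionSpec(b.ranges, atom_class="heavy", name_patterns=b.name_patterns)
    ia = select_indices(frame, a_heavy)
    ib = select_indices(frame, b_heavy)
    if ia.size == 0 or ib.size == 0:
        raise BuildError("clash_check requires non-empty heavy-atom selections")
    if set(ia.tolist()) & set(ib.tolist()):
        raise BuildError("clash_check selections overlap")
    xa = frame.coords[ia]
    xb = frame.coords[ib]
    tree_b = cKDTree(xb)
    dmin, _ = tree_b.query(xa, k=1)
    pairs = cKDTree(xa).query_ball_tree(tree_b, r=cutoff_A)
    offending = []
    for i_local, hits in enumerate(pairs):
        for j_local in hits:
            d = float(np.linalg.norm(xa[i_local] - xb[j_local]))
            if d < cutoff_A:
                offending.append(
                    (
                        frame.atoms[ia[i_local]].key,
                        frame.atoms[ib[j_local]].key,
                        d,
                    )
                )
    offending.sort(key=lambda p: p[2])
    return ClashReport(
        min_distance_A=float(dmin.min()),
        n_pairs_below_cutoff=len(offending),
        offending_pairs=offending,
    )
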