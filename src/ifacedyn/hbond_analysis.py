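"""Interfacial hydrogen-bond detection and occupancy statistics.

A hydrogen bond exists in a frame when the donor–acceptor heavy-atom
distance is below ``max_da_distance_A`` and the angle at the donor between
the D→H and D→A directions is below ``max_angle_deg`` for at least one
hydrogen bound to the donor.  The survival ratio of a bond over one replica
is the fraction of analyzed frames in which it is detected; replica ratios
are then summarized as max / average / sample standard deviation, and bonds
are retained when their maximum ratio reaches the retention threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ifacedyn.structure_io import (
    Frame,
    SelectionSpec,
    Trajectory,
    select_indices,
)

#: Maximum covalent D–H distance used to attach hydrogens to donor heavy atoms.
DONOR_H_DISTANCE_A = 1.2

#: Default loop classification ranges on the antigen chain (author numbering).
DEFAULT_LOOP_RANGES = {
    "N-terminal": (25, 33),
    "BC": (55, 64),
    "FG": (127, 135),
}

#: Display order of loop classes in bond tables.
LOOP_ORDER = ("N-terminal", "FG", "BC", "other")


class HBondError(Exception):
    pass


class NoHydrogensError(HBondError):
    """The frame carries no hydrogens; geometric detection needs them."""


class LoopConfigError(HBondError):
    """Configured loop ranges overlap."""


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals (table convention)."""
    return math.floor(abs(x) * 100.0 + 0.5) / 100.0 * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class HBondGeometry:
    max_da_distance_A: float = 3.5
    max_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.max_da_distance_A <= 0 or self.max_angle_deg <= 0:
            raise ValueError("geometry cutoffs must be positive")


@dataclass(frozen=True)
class HBondKey:
    """Direction-specific identity of a donor→acceptor contact.

    Each endpoint is ``(chain_id, residue_seq, residue_name, atom_name)``;
    the donor atom is the heavy atom carrying the hydrogen.  The same atom
    pair in swapped roles is a distinct key.
    """

    donor: tuple[str, int, str, str]
    acceptor: tuple[str, int, str, str]

    def __str__(self) -> str:
        d, a = self.donor, self.acceptor
        return f"{d[2]}{d[1]}_{d[0]} {d[3]} -> {a[2]}{a[1]}_{a[0]} {a[3]}"


@dataclass
class SurvivalRecord:
    key: HBondKey
    ratios: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, r in self.ratios.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"ratio {r} for {label} outside [0, 1]")


@dataclass
class BondSummary:
    key: HBondKey
    per_run: dict[str, float]
    max: float
    ave: float
    std: float
    loop_class: str = "other"


_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}


def _donor_acceptor_indices(
    frame: Frame, spec: SelectionSpec, h_tree: cKDTree | None, h_idx: np.ndarray
) -> tuple[list[tuple[int, list[int]]], list[int]]:
    """Split a side into donors (with their hydrogen indices) and acceptors."""
    heavy_spec = SelectionSpec(spec.ranges, atom_class="heavy", name_patterns=spec.name_patterns)
    idx = select_indices(frame, heavy_spec)
    donors: list[tuple[int, list[int]]] = []
    acceptors: list[int] = []
    for i in idx:
        atom = frame.atoms[i]
        if atom.element not in _DONOR_ACCEPTOR_ELEMENTS:
            continue
        acceptors.append(int(i))
        if h_tree is not None:
            near_h = h_tree.query_ball_point(atom.position, DONOR_H_DISTANCE_A)
            if near_h:
                donors.append((int(i), [int(h_idx[j]) for j in near_h]))
    return donors, acceptors


def detect_hbonds(
    frame: Frame,
    side_a: SelectionSpec,
    side_b: SelectionSpec,
    geom: HBondGeometry = HBondGeometry(),
) -> set[HBondKey]:
    """All cross-side donor→acceptor contacts meeting the geometric criteria.

    Both directions are scanned (donor on either side).  N and O heavy atoms
    are acceptor-capable; they are donor-capable when a hydrogen lies within
    1.2 Å in this frame.

    Raises
    ------
    NoHydrogensError
        If the frame contains no hydrogens at all — there is no silent
        distance-only fallback.
    """
    all_h = select_indices(frame, SelectionSpec(atom_class="hydrogen"))
    if all_h.size == 0:
        raise NoHydrogensError(
            "frame has no hydrogens; geometric H-bond detection requires "
            "hydrogen-bearing input"
        )
    h_tree = cKDTree(frame.coords[all_h])

    sides = []
    for spec in (side_a, side_b):
        sides.append(_donor_acceptor_indices(frame, spec, h_tree, all_h))
    (don_a, acc_a), (don_b, acc_b) = sides
    overlap = ({i for i, _ in don_a} | set(acc_a)) & ({i for i, _ in don_b} | set(acc_b))
    if overlap:
        raise HBondError("side_a and side_b selections overlap")

    found: set[HBondKey] = set()
    cos_max = math.cos(math.radians(geom.max_angle_deg))
    for donors, acceptors in ((don_a, acc_b), (don_b, acc_a)):
        if not donors or not acceptors:
            continue
        acc_coords = frame.coords[acceptors]
        acc_tree = cKDTree(acc_coords)
        for di, h_indices in donors:
            d_pos = frame.atoms[di].position
            near = acc_tree.query_ball_point(d_pos, geom.max_da_distance_A)
            for aj_local in near:
                ai = acceptors[aj_local]
                a_pos = frame.atoms[ai].position
                da = a_pos - d_pos
                da_dist = float(np.linalg.norm(da))
                if da_dist >= geom.max_da_distance_A or da_dist < 1e-9:
                    continue
                for hi in h_indices:
                    dh = frame.atoms[hi].position - d_pos
                    nh = float(np.linalg.norm(dh))
                    if nh < 1e-9:
                        continue
                    cosang = float(np.dot(dh, da)) / (nh * da_dist)
                    if cosang > cos_max:  # angle strictly below the cutoff
                        d_atom = frame.atoms[di]
                        a_atom = frame.atoms[ai]
                        found.add(
                            HBondKey(
                                donor=(
                                    d_atom.chain_id,
                                    d_atom.residue_seq,
                                    d_atom.residue_name,
                                    d_atom.atom_name,
                                ),
                                acceptor=(
                                    a_atom.chain_id,
                                    a_atom.residue_seq,
                                    a_atom.residue_name,
                                    a_atom.atom_name,
                                ),
                            )
                        )
                        break
    return found


def survival_ratio(
    traj: Trajectory,
    side_a: SelectionSpec,
    side_b: SelectionSpec,
    geom: HBondGeometry = HBondGeometry(),
    equilibration_fraction: float = 0.0,
) -> list[SurvivalRecord]:
    """Per-bond detected-frame fraction over one replica.

    The first ``ceil(equilibration_fraction * n)`` frames are discarded
    before counting.  Bonds never detected are absent from the result.
    """
    if not (0.0 <= equilibration_fraction < 1.0):
        raise ValueError("equilibration_fraction must be in [0, 1)")
    n = len(traj.frames)
    start = math.ceil(equilibration_fraction * n)
    analyzed = traj.frames[start:]
    if not analyzed:
        raise HBondError("no frames left to analyze after equilibration discard")
    counts: dict[HBondKey, int] = {}
    for frame in analyzed:
        for key in detect_hbonds(frame, side_a, side_b, geom):
            counts[key] = counts.get(key, 0) + 1
    label = traj.replica_label or "run"
    return [
        SurvivalRecord(key, {label: c / len(analyzed)})
        for key, c in sorted(counts.items(), key=lambda kv: str(kv[0]))
    ]


def classify_loop(
    residue_seq: int,
    loop_ranges: dict[str, tuple[int, int]] = DEFAULT_LOOP_RANGES,
) -> str:
    """Loop class of an antigen residue number; outside every range → "other"."""
    spans = sorted(loop_ranges.items(), key=lambda kv: kv[1][0])
    for (_, (s1, e1)), (n2, (s2, e2)) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise LoopConfigError(f"loop ranges overlap at {n2}")
    for name, (start, end) in loop_ranges.items():
        if start <= residue_seq <= end:
            return name
    return "other"


def summarize_replicas(
    records: list[SurvivalRecord],
    replica_labels: list[str] | None = None,
    loop_ranges: dict[str, tuple[int, int]] = DEFAULT_LOOP_RANGES,
    antigen_chain: str | None = None,
) -> list[BondSummary]:
    """Merge per-replica survival records into max/ave/std bond summaries.

    A replica in which a bond was never detected contributes a ratio of 0.
    The standard deviation is the sample (n−1) form; with a single replica
    it is reported as 0 with a warning.  The loop class comes from the
    donor-side residue on the antigen chain (the non-antigen endpoint if the
    donor sits on the antibody).
    """
    merged: dict[HBondKey, dict[str, float]] = {}
    seen_labels: list[str] = []
    for rec in records:
        slot = merged.setdefault(rec.key, {})
        for label, ratio in rec.ratios.items():
            slot[label] = ratio
            if label not in seen_labels:
                seen_labels.append(label)
    labels = replica_labels if replica_labels is not None else seen_labels
    if not labels:
        return []
    if len(labels) == 1:
        warnings.warn("single replica: std reported as 0", stacklevel=2)

    summaries = []
    for key, ratios in merged.items():
        per_run = {lab: float(ratios.get(lab, 0.0)) for lab in labels}
        vals = np.array(list(per_run.values()))
        std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if antigen_chain is not None:
            res = key.donor if key.donor[0] == antigen_chain else key.acceptor
            loop = classify_loop(res[1], loop_ranges)
        else:
            loop = classify_loop(key.donor[1], loop_ranges)
        summaries.append(
            BondSummary(
                key=key,
                per_run=per_run,
                max=float(vals.max()),
                ave=float(vals.mean()),
                std=std,
                loop_class=loop,
            )
        )
    return summaries


def filter_retained(
    summaries: list[BondSummary],
    threshold: float = 0.2,
) -> list[BondSummary]:
    """Bonds whose maximum ratio reaches the threshold, in table order.

    The comparison is inclusive after rounding the maximum to 2 decimals
    (printed tables retain rows with max exactly at the threshold).  Rows
    are ordered by loop class (N-terminal, FG, BC, other), then descending
    maximum, then descending first-replica ratio.
    """
    kept = [s for s in summaries if _round2(s.max) >= threshold]

    def sort_key(s: BondSummary):
        loop_rank = (
            LOOP_ORDER.index(s.loop_class)
            if s.loop_class in LOOP_ORDER
            else len(LOOP_ORDER)
        )
        first = next(iter(s.per_run.values())) if s.per_run else 0.0
        return (loop_rank, -s.max, -first, str(s.key))

    return sorted(kept, key=sort_key)
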