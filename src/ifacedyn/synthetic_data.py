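"""Synthetic two-body complexes with scripted, exactly-known ground truth.

The generator lays out a toy antigen (a terminal loop on an interface rail
plus a rigid body) facing a toy antibody across a gap.  Scheduled hydrogen
bonds are realized geometrically: per frame, each scheduled acceptor atom is
placed either inside (distance 2.8 Å, angle ≤ 20°) or outside (6.0 Å) the
detection criteria according to an independent Bernoulli draw at the
scheduled occupancy.  Rotation scenarios, water shells, and per-atom
nonbonded parameters are emitted alongside so every pipeline stage can be
checked against known values without any external input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ifacedyn.complex_builder import RotationPlan, clash_check, plan_rotation, rotate_segment
from ifacedyn.hbond_analysis import HBondKey
from ifacedyn.interface_metrics import ParamEntry, ParamTable
from ifacedyn.structure_io import (
    AtomRecord,
    Frame,
    ResidueRange,
    SelectionSpec,
    Trajectory,
)

_RAIL_SPACING = 8.0  # Å between interface slots; keeps scheduled sites independent
_ON_DISTANCE = 2.8
_OFF_DISTANCE = 6.0
_BODY_Y = -6.0
_ANTIBODY_Y = 10.0
_EXTRA_Z = 3.0
_SHARED_DONOR_ANGLES = (0.0, 20.0, -20.0)  # deg, all below the 30° cutoff

#: Round-number nonbonded parameters by element (charge e, eps kcal/mol,
#: rmin/2 Å, SASA radius Å) — embedded so tests need no force-field files.
_ELEMENT_PARAMS = {
    "C": (0.0, 0.10, 2.00, 1.70),
    "N": (-0.40, 0.20, 1.85, 1.55),
    "O": (-0.50, 0.15, 1.70, 1.52),
    "H": (0.30, 0.05, 0.40, 1.20),
}


class GenerationError(Exception):
    """The requested toy geometry is unrealizable."""


@dataclass(frozen=True)
class BondSchedule:
    key: HBondKey
    occupancy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class RotationScenario:
    segment: ResidueRange
    angles_deg: np.ndarray  # one entry per frame

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)


@dataclass
class WaterShellSpec:
    n_waters: int
    inner_A: float = 3.0
    outer_A: float = 6.0

    def __post_init__(self) -> None:
        if not (self.outer_A >= self.inner_A > 0):
            raise ValueError("need outer_A >= inner_A > 0")


def default_bond_schedules(
    antigen_chain: str = "P", heavy_chain: str = "H"
) -> list[BondSchedule]:
    """A small mixed-occupancy schedule exercising every donor placement."""
    P, H = antigen_chain, heavy_chain
    return [
        BondSchedule(HBondKey((P, 30, "ARG", "N"), (H, 31, "ASN", "O")), 0.9),
        BondSchedule(HBondKey((P, 29, "ASP", "N"), (H, 33, "GLY", "O")), 0.6),
        BondSchedule(HBondKey((P, 30, "ARG", "NH1"), (H, 100, "ASP", "OD1")), 0.3),
        BondSchedule(HBondKey((H, 99, "ASN", "ND2"), (P, 29, "ASP", "OD1")), 0.5),
    ]


@dataclass
class ToySpec:
    """Recipe for a synthetic trajectory with known ground truth."""

    n_frames: int = 100
    seed: int = 0
    antigen_chain: str = "P"
    loop_residues: tuple[int, int] = (25, 33)
    body_residues: tuple[int, int] = (34, 53)
    antibody_chain: str = "H"
    bond_schedules: list[BondSchedule] | None = None
    rotation: RotationScenario | None = None
    water_shell: WaterShellSpec | None = None
    dt_ps: float = 10.0
    replica_label: str = "Equ1"

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.bond_schedules is None:
            self.bond_schedules = default_bond_schedules(
                self.antigen_chain, self.antibody_chain
            )


@dataclass
class GroundTruth:
    """Known values the pipeline must recover from a generated fixture."""

    occupancies: dict[str, float] = field(default_factory=dict)
    realized_counts: dict[str, int] = field(default_factory=dict)
    n_frames: int = 0
    angles_deg: list[float] | None = None
    expected_water_counts: list[int] | None = None
    clash_free: bool = True

    def to_json(self, path: str | Path) -> None:
        payload = {
            "occupancies": self.occupancies,
            "realized_counts": self.realized_counts,
            "n_frames": self.n_frames,
            "angles_deg": self.angles_deg,
            "expected_water_counts": self.expected_water_counts,
            "clash_free": self.clash_free,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = {
    # name -> (dx, dy, dz); dy is signed toward the interface per side
    "N": (0.0, 0.0, 0.0),
    "H": (0.0, 1.0, 0.0),
    "CA": (1.5, -1.0, 0.0),
    "C": (3.0, 0.0, 0.0),
    "O": (3.0, -1.5, 0.5),
}

_RESNAMES = [
    "ALA", "ARG", "ASN", "ASP", "GLY", "GLU", "LEU", "LYS", "PRO", "SER", "THR", "TYR",
]


def _resname_for(chain: str, seq: int, named: dict[tuple[str, int], str]) -> str:
    return named.get((chain, seq), _RESNAMES[seq % len(_RESNAMES)])


@dataclass
class _Site:
    schedule: BondSchedule
    donor_index: int
    acceptor_index: int
    h_position: np.ndarray
    donor_position: np.ndarray
    on_position: np.ndarray
    off_position: np.ndarray


class _ToyBuilder:
    """Builds the fixed topology and the per-frame acceptor placements."""

    def __init__(self, spec: ToySpec):
        self.spec = spec
        self.atoms: list[AtomRecord] = []
        self._index: dict[tuple[str, int, str], int] = {}
        self.sites: list[_Site] = []
        self._validate_schedules()
        # acceptor atoms are placed by their schedule site, never by the
        # backbone builder, even when they carry a backbone name like "O"
        self._reserved = {
            (s.key.acceptor[0], s.key.acceptor[1], s.key.acceptor[3])
            for s in spec.bond_schedules
        }
        named = self._named_residues()
        self._build_antigen(named)
        self._build_antibody(named)
        self._build_sites()

    # -- validation --------------------------------------------------------

    def _validate_schedules(self) -> None:
        spec = self.spec
        seen_pairs: set[tuple] = set()
        acceptors: set[tuple] = set()
        donor_counts: dict[tuple, int] = {}
        lo, hi = spec.loop_residues
        for sched in spec.bond_schedules:
            key = sched.key
            pair = (key.donor, key.acceptor)
            if pair in seen_pairs:
                raise GenerationError(f"duplicate schedule for {key}")
            seen_pairs.add(pair)
            d_atom = key.donor[:2] + (key.donor[3],)
            a_atom = key.acceptor[:2] + (key.acceptor[3],)
            if a_atom in acceptors:
                raise GenerationError(
                    f"acceptor atom {a_atom} scheduled twice: unrealizable"
                )
            acceptors.add(a_atom)
            donor_counts[d_atom] = donor_counts.get(d_atom, 0) + 1
            if donor_counts[d_atom] > len(_SHARED_DONOR_ANGLES):
                raise GenerationError(
                    f"donor atom {d_atom} scheduled more than "
                    f"{len(_SHARED_DONOR_ANGLES)} times: sites would clash"
                )
            if key.donor[3] in _BACKBONE_OFFSETS and key.donor[3] != "N":
                raise GenerationError(
                    f"backbone atom {key.donor[3]} cannot donate (no hydrogen); "
                    "use the backbone N or a side-chain-style atom name"
                )
            chains = {key.donor[0], key.acceptor[0]}
            if chains != {spec.antigen_chain, spec.antibody_chain}:
                raise GenerationError(
                    f"schedule {key} must pair chain {spec.antigen_chain} "
                    f"with chain {spec.antibody_chain}"
                )
            for endpoint in (key.donor, key.acceptor):
                if endpoint[0] == spec.antigen_chain and not (lo <= endpoint[1] <= hi):
                    raise GenerationError(
                        f"antigen residue {endpoint[1]} outside the loop "
                        f"range {spec.loop_residues}"
                    )

    def _named_residues(self) -> dict[tuple[str, int], str]:
        named: dict[tuple[str, int], str] = {}
        for sched in self.spec.bond_schedules:
            for chain, seq, resname, _ in (sched.key.donor, sched.key.acceptor):
                prev = named.setdefault((chain, seq), resname)
                if prev != resname:
                    raise GenerationError(
                        f"residue {chain}:{seq} named both {prev} and {resname}"
                    )
        return named

    # -- atom placement ----------------------------------------------------

    def _add_atom(
        self, chain: str, seq: int, resname: str, name: str, pos: np.ndarray
    ) -> int:
        key = (chain, seq, name)
        if key in self._index:
            raise GenerationError(f"atom {key} placed twice")
        element = next(ch for ch in name if ch.isalpha()).upper()
        atom = AtomRecord(
            serial=len(self.atoms) + 1,
            atom_name=name,
            element=element,
            residue_name=resname,
            residue_seq=seq,
            chain_id=chain,
            position=np.asarray(pos, dtype=float),
            is_hydrogen=(element == "H"),
            is_water=False,
        )
        self._index[key] = len(self.atoms)
        self.atoms.append(atom)
        return self._index[key]

    def _build_backbone(
        self, chain: str, seq: int, resname: str, base: np.ndarray, toward: float
    ) -> None:
        for name, (dx, dy, dz) in _BACKBONE_OFFSETS.items():
            if (chain, seq, name) in self._reserved:
                continue
            pos = base + np.array([dx, toward * dy, dz])
            self._add_atom(chain, seq, resname, name, pos)

    def _build_antigen(self, named: dict[tuple[str, int], str]) -> None:
        spec = self.spec
        lo, hi = spec.loop_residues
        for seq in range(lo, hi + 1):
            base = np.array([(seq - lo) * _RAIL_SPACING, 0.0, 0.0])
            self._build_backbone(
                spec.antigen_chain, seq, _resname_for(spec.antigen_chain, seq, named), base, +1.0
            )
        blo, bhi = spec.body_residues
        for seq in range(blo, bhi + 1):
            base = np.array([(seq - blo) * 3.8, _BODY_Y, 0.0])
            self._build_backbone(
                spec.antigen_chain, seq, _resname_for(spec.antigen_chain, seq, named), base, -1.0
            )

    def _build_antibody(self, named: dict[tuple[str, int], str]) -> None:
        spec = self.spec
        residues = sorted(
            {
                endpoint[1]
                for sched in spec.bond_schedules
                for endpoint in (sched.key.donor, sched.key.acceptor)
                if endpoint[0] == spec.antibody_chain
            }
        ) or [1]
        for m, seq in enumerate(residues):
            base = np.array([m * _RAIL_SPACING, _ANTIBODY_Y, 0.0])
            self._build_backbone(
                spec.antibody_chain, seq, _resname_for(spec.antibody_chain, seq, named), base, -1.0
            )

    def _build_sites(self) -> None:
        """Place scheduled donor hydrogens and the two acceptor positions."""
        spec = self.spec
        lo, _ = spec.loop_residues
        extra_per_residue: dict[tuple[str, int], int] = {}
        per_donor_atom: dict[tuple, int] = {}
        for sched in spec.bond_schedules:
            key = sched.key
            d_chain, d_seq, d_resname, d_name = key.donor
            on_antigen = d_chain == spec.antigen_chain
            toward = +1.0 if on_antigen else -1.0

            d_key = (d_chain, d_seq, d_name)
            if d_key in self._index:
                donor_idx = self._index[d_key]
                donor_pos = self.atoms[donor_idx].position
            else:
                # extra (side-chain-like) donor on its own z lane
                if on_antigen:
                    base_x = (d_seq - lo) * _RAIL_SPACING
                    base_y = 0.0
                else:
                    base_x = self.atoms[self._index[(d_chain, d_seq, "N")]].position[0]
                    base_y = _ANTIBODY_Y
                k = extra_per_residue.get((d_chain, d_seq), 0)
                extra_per_residue[(d_chain, d_seq)] = k + 1
                donor_pos = np.array([base_x, base_y, _EXTRA_Z * (k + 1)])
                donor_idx = self._add_atom(d_chain, d_seq, d_resname, d_name, donor_pos)
                self._add_atom(
                    d_chain,
                    d_seq,
                    d_resname,
                    "H" + d_name,
                    donor_pos + np.array([0.0, toward, 0.0]),
                )
                h_pos = donor_pos + np.array([0.0, toward, 0.0])
            h_pos = donor_pos + np.array([0.0, toward, 0.0])

            share = per_donor_atom.get(d_key, 0)
            per_donor_atom[d_key] = share + 1
            alpha = math.radians(_SHARED_DONOR_ANGLES[share])
            direction = np.array(
                [math.sin(alpha), toward * math.cos(alpha), 0.0]
            )
            on_pos = donor_pos + _ON_DISTANCE * direction
            off_pos = donor_pos + _OFF_DISTANCE * direction

            a_chain, a_seq, a_resname, a_name = key.acceptor
            acceptor_idx = self._add_atom(a_chain, a_seq, a_resname, a_name, on_pos)
            self.sites.append(
                _Site(sched, donor_idx, acceptor_idx, h_pos, donor_pos, on_pos, off_pos)
            )


def params_for_frame(frame: Frame) -> ParamTable:
    """Round-number nonbonded parameters covering every atom of a frame."""
    table: ParamTable = {}
    for atom in frame.atoms:
        q, eps, rmin_half, radius = _ELEMENT_PARAMS.get(
            atom.element, _ELEMENT_PARAMS["C"]
        )
        table[atom.key] = ParamEntry(
            chain_id=atom.chain_id,
            residue_seq=atom.residue_seq,
            atom_name=atom.atom_name,
            charge=q,
            epsilon=eps,
            rmin_half=rmin_half,
            radius=radius,
        )
    return table


def generate_toy_complex(spec: ToySpec) -> tuple[Trajectory, ParamTable, GroundTruth]:
    """Deterministic toy trajectory realizing the scheduled bond occupancies."""
    builder = _ToyBuilder(spec)
    rng = np.random.default_rng(spec.seed)
    frames: list[Frame] = []
    realized = {str(site.schedule.key): 0 for site in builder.sites}
    base = Frame(builder.atoms, frame_index=0, time_ps=0.0)
    base_coords = base.coords.copy()
    for t in range(spec.n_frames):
        coords = base_coords.copy()
        for site in builder.sites:
            on = bool(rng.random() < site.schedule.occupancy)
            coords[site.acceptor_index] = site.on_position if on else site.off_position
            if on:
                realized[str(site.schedule.key)] += 1
        frames.append(base.with_coords(coords, frame_index=t, time_ps=t * spec.dt_ps))

    traj = Trajectory(frames, replica_label=spec.replica_label)
    truth = GroundTruth(
        occupancies={str(s.schedule.key): s.schedule.occupancy for s in builder.sites},
        realized_counts=realized,
        n_frames=spec.n_frames,
    )

    if spec.water_shell is not None:
        traj, counts = place_water_shell(
            traj,
            ResidueRange(spec.antigen_chain, *spec.loop_residues),
            spec.water_shell.n_waters,
            spec.water_shell.inner_A,
            spec.water_shell.outer_A,
        )
        truth.expected_water_counts = counts

    report = clash_check(
        traj.frames[0],
        SelectionSpec.chains(spec.antigen_chain),
        SelectionSpec.chains(spec.antibody_chain),
        cutoff_A=2.0,
    )
    truth.clash_free = report.clash_free
    params = params_for_frame(traj.frames[0])
    return traj, params, truth


def generate_rotation_trajectory(spec: ToySpec) -> tuple[Trajectory, GroundTruth]:
    """Trajectory whose segment follows a scripted rigid-rotation angle series.

    Frame t holds the base complex with the segment rotated by
    ``angles_deg[t]`` about the away-from-partner hinge axis; the partner
    side never moves.  All scheduled bonds are ON in the base geometry so a
    nonzero angle visibly breaks them.
    """
    if spec.rotation is None:
        loop = ResidueRange(spec.antigen_chain, *spec.loop_residues)
        spec.rotation = RotationScenario(
            loop, np.linspace(90.0, 0.0, spec.n_frames)
        )
    scenario = spec.rotation
    if len(scenario.angles_deg) != spec.n_frames:
        raise GenerationError("angle series length must equal n_frames")

    all_on = ToySpec(
        n_frames=1,
        seed=spec.seed,
        antigen_chain=spec.antigen_chain,
        loop_residues=spec.loop_residues,
        body_residues=spec.body_residues,
        antibody_chain=spec.antibody_chain,
        bond_schedules=[BondSchedule(s.key, 1.0) for s in spec.bond_schedules],
        dt_ps=spec.dt_ps,
        replica_label=spec.replica_label,
    )
    base_traj, _, _ = generate_toy_complex(all_on)
    base = base_traj.frames[0]

    plan90 = plan_rotation(
        base,
        scenario.segment,
        SelectionSpec.chains(spec.antibody_chain),
        angle_deg=90.0,
    )
    sign = 1.0 if plan90.angle_deg >= 0 else -1.0
    frames = []
    for t, angle in enumerate(scenario.angles_deg):
        plan = RotationPlan(
            scenario.segment,
            plan90.hinge_residue,
            plan90.axis_unit,
            plan90.pivot,
            sign * float(angle),
        )
        rotated = rotate_segment(base, plan)
        frames.append(
            rotated.with_coords(rotated.coords, frame_index=t, time_ps=t * spec.dt_ps)
        )
    traj = Trajectory(frames, replica_label=spec.replica_label)
    truth = GroundTruth(
        occupancies={str(s.key): 1.0 for s in spec.bond_schedules},
        n_frames=spec.n_frames,
        angles_deg=[float(a) for a in scenario.angles_deg],
    )
    return traj, truth


def place_water_shell(
    traj: Trajectory,
    target_loop: ResidueRange,
    n_waters: int,
    inner_A: float = 3.0,
    outer_A: float = 6.0,
    water_chain: str = "W",
) -> tuple[Trajectory, list[int]]:
    """Add a deterministic water shell around the loop's central residue.

    Waters sit on a spiral in the plane orthogonal to the rail axis at radii
    spanning [inner, outer] from the central residue's backbone N.  The
    exact per-frame count of waters within 4 Å of any loop heavy atom is
    returned alongside (computed by brute force — this is the ground truth).
    """
    if not (outer_A >= inner_A > 0):
        raise GenerationError("need outer_A >= inner_A > 0")
    frame0 = traj.frames[0]
    loop_res = sorted(
        {
            a.residue_seq
            for a in frame0.atoms
            if target_loop.contains(a.chain_id, a.residue_seq)
        }
    )
    if not loop_res:
        raise GenerationError(f"loop {target_loop} resolves to no residues")

    # heavy-atom positions over every frame: scheduled acceptors move, so a
    # shell clearing frame 0 alone could still collide later
    all_heavy = np.concatenate(
        [
            np.array(
                [a.position for a in fr.atoms if not a.is_hydrogen and not a.is_water]
            )
            for fr in traj.frames
        ]
    )

    def shell_positions(anchor: np.ndarray) -> np.ndarray:
        # spiral over a forward-facing spherical patch (y > 0, limited x
        # spread) so the shell stays clear of the body rail behind the loop
        # and of the neighbouring rail slots
        golden_frac = (math.sqrt(5.0) - 1.0) / 2.0
        pos = []
        for i in range(n_waters):
            r = (
                inner_A
                if n_waters == 1
                else inner_A + (outer_A - inner_A) * i / (n_waters - 1)
            )
            frac = 0.5 if n_waters == 1 else i / (n_waters - 1)
            ux = -0.5 + frac  # in [-0.5, 0.5]
            s = math.sqrt(1.0 - ux * ux)
            psi = -1.2 + 2.4 * ((0.5 + i * golden_frac) % 1.0)
            direction = np.array([ux, s * math.cos(psi), s * math.sin(psi)])
            pos.append(anchor + r * direction)
        return np.array(pos)

    # anchor on the loop residue closest to the middle whose shell stays
    # clear of the protein in every frame
    mid = len(loop_res) // 2
    candidates = sorted(range(len(loop_res)), key=lambda i: (abs(i - mid), i))
    positions = None
    for ci in candidates:
        anchor = next(
            (
                a.position
                for a in frame0.atoms
                if a.chain_id == target_loop.chain_id
                and a.residue_seq == loop_res[ci]
                and a.atom_name == "N"
            ),
            None,
        )
        if anchor is None:
            continue
        cand = shell_positions(anchor)
        clearance = np.linalg.norm(
            all_heavy[None, :, :] - cand[:, None, :], axis=2
        ).min()
        if clearance >= 1.8:
            positions = cand
            break
    if positions is None:
        raise GenerationError("water shell clashes with protein atoms at every anchor")
    if n_waters > 1:
        from scipy.spatial.distance import pdist

        if pdist(positions).min() < 1.2:
            raise GenerationError("water band too dense: waters would clash")

    water_atoms = []
    for i, pos in enumerate(positions):
        for name, offset in (
            ("O", np.zeros(3)),
            ("H1", np.array([0.6, 0.8, 0.0])),
            ("H2", np.array([-0.6, 0.8, 0.0])),
        ):
            water_atoms.append(
                AtomRecord(
                    serial=len(frame0.atoms) + len(water_atoms) + 1,
                    atom_name=name,
                    element=name[0],
                    residue_name="HOH",
                    residue_seq=i + 1,
                    chain_id=water_chain,
                    position=pos + offset,
                    is_hydrogen=name.startswith("H"),
                    is_water=True,
                )
            )

    counts: list[int] = []
    new_frames = []
    for frame in traj.frames:
        atoms = list(frame.atoms) + [
            AtomRecord(
                serial=a.serial,
                atom_name=a.atom_name,
                element=a.element,
                residue_name=a.residue_name,
                residue_seq=a.residue_seq,
                chain_id=a.chain_id,
                position=a.position.copy(),
                is_hydrogen=a.is_hydrogen,
                is_water=a.is_water,
            )
            for a in water_atoms
        ]
        new_frames.append(
            Frame(atoms, frame_index=frame.frame_index, time_ps=frame.time_ps,
                  metadata=dict(frame.metadata))
        )
        loop_heavy = np.array(
            [
                a.position
                for a in frame.atoms
                if target_loop.contains(a.chain_id, a.residue_seq)
                and not a.is_hydrogen
            ]
        )
        n_in = 0
        for p in positions:
            if np.linalg.norm(loop_heavy - p, axis=1).min() <= 4.0:
                n_in += 1
        counts.append(n_in)
    return Trajectory(new_frames, replica_label=traj.replica_label), counts


def write_fixture(
    out_dir: str | Path,
    traj: Trajectory,
    params: ParamTable | None,
    truth: GroundTruth,
) -> None:
    """Write traj.pdb, params.tsv and truth.json into a fixture directory."""
    from ifacedyn.interface_metrics import write_param_table
    from ifacedyn.structure_io import write_structure

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_structure(traj, out / "traj.pdb")
    if params is not None:
        write_param_table(params, out / "params.tsv")
    truth.to_json(out / "truth.json")
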