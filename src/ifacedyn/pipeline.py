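"""End-to-end orchestration: scenario building, per-replica analysis, and
publication-style bond tables.

Also hosts the printed-table ingest path: per-replica survival ratios
transcribed from published tables can be fed straight into the replica
summarizer, which recomputes max/ave/std and the retention filter without
any trajectory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ifacedyn import __version__
from ifacedyn.complex_builder import (
    BuildError,
    ClashReport,
    clash_check,
    plan_rotation,
    rotate_segment,
    truncate_segment,
)
from ifacedyn.hbond_analysis import (
    DEFAULT_LOOP_RANGES,
    BondSummary,
    HBondGeometry,
    HBondKey,
    SurvivalRecord,
    classify_loop,
    detect_hbonds,
    filter_retained,
    summarize_replicas,
    survival_ratio,
)
from ifacedyn.interface_metrics import (
    ParamTable,
    buried_sasa,
    count_waters_within,
    interaction_energy,
    read_param_table,
)
from ifacedyn.replica_stats import (
    ComparisonResult,
    DistributionSummary,
    MetricSeries,
    compare_groups,
    discard_equilibration,
    distribution_summary,
)
from ifacedyn.structure_io import (
    Frame,
    ResidueRange,
    SelectionSpec,
    Trajectory,
    read_structure,
)

SCENARIOS = ("native", "n-truncated", "n-rotated", "igv-rotated")


class ConfigError(Exception):
    pass


@dataclass
class RunConfig:
    """Single source of truth for every threshold and addressing choice."""

    inputs: dict[str, str] = field(default_factory=dict)  # label -> native PDB
    trajectories: dict[str, dict[str, str]] = field(default_factory=dict)
    params_path: str | None = None
    antigen_chain: str = "P"
    antibody_chains: tuple[str, ...] = ("H", "L")
    n_loop: tuple[int, int] = (25, 33)
    igv: tuple[int, int] = (34, 143)
    loop_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_RANGES)
    )
    scenarios: tuple[str, ...] = SCENARIOS
    rotation_angle_deg: float = 90.0
    hbond_distance_A: float = 3.5
    hbond_angle_deg: float = 30.0
    retention_threshold: float = 0.2
    water_radius_A: float = 4.0
    clash_cutoff_A: float = 2.0
    equilibration_fraction: float = 0.2
    sasa_points: int = 960
    energy_cutoff_A: float = 12.0
    energy_switch_on_A: float = 10.0
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0
    out_dir: str = "report"

    def __post_init__(self) -> None:
        self.antibody_chains = tuple(self.antibody_chains)
        self.scenarios = tuple(self.scenarios)
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ConfigError(f"unknown scenarios {sorted(unknown)}")

    @property
    def hbond_geometry(self) -> HBondGeometry:
        return HBondGeometry(self.hbond_distance_A, self.hbond_angle_deg)

    @property
    def antigen_spec(self) -> SelectionSpec:
        return SelectionSpec.chains(self.antigen_chain)

    @property
    def antibody_spec(self) -> SelectionSpec:
        return SelectionSpec.chains(*self.antibody_chains)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class ReportBundle:
    bond_tables: dict[str, list[BondSummary]] = field(default_factory=dict)
    metric_series: list[MetricSeries] = field(default_factory=list)
    distributions: dict[tuple[str, str], DistributionSummary] = field(default_factory=dict)
    water_comparisons: list[ComparisonResult] = field(default_factory=list)
    clash_reports: dict[str, ClashReport] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def bond_table_frame(self, system: str) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.bond_tables[system], start=1):
            row = {
                "bond_no": i,
                "loop": s.loop_class,
                "residue": f"{s.key.donor[2]}{s.key.donor[1]}",
                "atom": s.key.donor[3],
                "partner_residue": f"{s.key.acceptor[2]}{s.key.acceptor[1]}_{s.key.acceptor[0]}",
                "partner_atom": s.key.acceptor[3],
            }
            row.update({k.lower(): v for k, v in s.per_run.items()})
            row.update({"max": s.max, "ave": s.ave, "std": s.std})
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for system in self.bond_tables:
            self.bond_table_frame(system).to_csv(
                out / f"bonds_{system}.tsv", sep="\t", index=False, float_format="%.6g"
            )
        if self.metric_series:
            long_rows = []
            for s in self.metric_series:
                for t, v in zip(s.times, s.values):
                    long_rows.append(
                        {
                            "system": s.system_label,
                            "replica": s.replica_label,
                            "metric": s.metric_name,
                            "time_ps": t,
                            "value": v,
                        }
                    )
            pd.DataFrame(long_rows).to_csv(
                out / "series.tsv", sep="\t", index=False, float_format="%.6g"
            )
        if self.water_comparisons:
            pd.DataFrame(
                [
                    {
                        "group_a": c.group_a,
                        "group_b": c.group_b,
                        "t": c.t_statistic,
                        "p": c.p_value,
                        "stars": c.stars,
                    }
                    for c in self.water_comparisons
                ]
            ).to_csv(out / "comparisons.tsv", sep="\t", index=False, float_format="%.6g")
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1))


# ---------------------------------------------------------------------------
# scenario construction
# ---------------------------------------------------------------------------

def build_scenario(
    frame: Frame,
    scenario: str,
    config: RunConfig,
) -> tuple[Frame, ClashReport | None]:
    """One scenario variant of a native complex frame, with its clash report."""
    n_loop = ResidueRange(config.antigen_chain, *config.n_loop)
    igv = ResidueRange(config.antigen_chain, *config.igv)
    if scenario == "native":
        return frame, None
    if scenario == "n-truncated":
        return truncate_segment(frame, n_loop), None
    if scenario in ("n-rotated", "igv-rotated"):
        segment = n_loop if scenario == "n-rotated" else igv
        plan = plan_rotation(
            frame, segment, config.antibody_spec, config.rotation_angle_deg
        )
        built = rotate_segment(frame, plan)
        report = clash_check(
            built,
            SelectionSpec((segment,)),
            config.antibody_spec,
            cutoff_A=config.clash_cutoff_A,
        )
        if not report.clash_free:
            raise BuildError(
                f"scenario {scenario}: {report.n_pairs_below_cutoff} clashing "
                f"pairs below {config.clash_cutoff_A} Å "
                f"(closest {report.min_distance_A:.2f} Å)"
            )
        return built, report
    raise ConfigError(f"unknown scenario {scenario!r}")


def build_all_scenarios(
    config: RunConfig,
    native_frames: dict[str, Frame] | None = None,
) -> tuple[dict[str, Frame], dict[str, ClashReport]]:
    """Every configured scenario for every native input.

    Two native inputs with the default four scenarios yield eight systems,
    labelled ``<input>_<scenario>``.
    """
    if native_frames is None:
        if not config.inputs:
            raise ConfigError("no native inputs configured")
        native_frames = {
            label: read_structure(path).frames[0]
            for label, path in config.inputs.items()
        }
    systems: dict[str, Frame] = {}
    reports: dict[str, ClashReport] = {}
    for label, frame in native_frames.items():
        for scenario in config.scenarios:
            name = f"{label}_{scenario}"
            built, report = build_scenario(frame, scenario, config)
            systems[name] = built
            if report is not None:
                reports[name] = report
    return systems, reports


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def analyze_system(
    system_label: str,
    replicas: list[Trajectory],
    config: RunConfig,
    params: ParamTable | None = None,
) -> tuple[list[BondSummary], list[MetricSeries]]:
    """Bond table and per-frame metric series for one system's replicas."""
    if not replicas:
        raise ConfigError(f"{system_label}: empty replica list")
    geom = config.hbond_geometry
    side_a, side_b = config.antigen_spec, config.antibody_spec

    records: list[SurvivalRecord] = []
    labels = []
    for traj in replicas:
        labels.append(traj.replica_label)
        records.extend(
            survival_ratio(
                traj, side_a, side_b, geom,
                equilibration_fraction=config.equilibration_fraction,
            )
        )
    summaries = summarize_replicas(
        records,
        replica_labels=labels,
        loop_ranges=config.loop_ranges,
        antigen_chain=config.antigen_chain,
    )
    table = filter_retained(summaries, config.retention_threshold)

    series: list[MetricSeries] = []
    for traj in replicas:
        times = np.array([f.time_ps for f in traj.frames])
        cols: dict[str, list[float]] = {
            "buried_sasa_A2": [],
            "n_hbonds": [],
            "n_waters": [],
        }
        if params is not None:
            cols["e_elec"] = []
            cols["e_vdw"] = []
            cols["e_total"] = []
        has_waters = any(a.is_water for a in traj.frames[0].atoms)
        for frame in traj.frames:
            cols["buried_sasa_A2"].append(
                buried_sasa(frame, side_a, side_b, n_points=config.sasa_points,
                            params=params)
            )
            cols["n_hbonds"].append(
                float(len(detect_hbonds(frame, side_a, side_b, geom)))
            )
            cols["n_waters"].append(
                float(count_waters_within(frame, side_a, config.water_radius_A))
                if has_waters
                else 0.0
            )
            if params is not None:
                e = interaction_energy(
                    frame, side_a, side_b, params,
                    cutoff_A=config.energy_cutoff_A,
                    switch_on_A=config.energy_switch_on_A,
                )
                cols["e_elec"].append(e.electrostatic)
                cols["e_vdw"].append(e.vdw)
                cols["e_total"].append(e.total)
        for name, values in cols.items():
            series.append(
                MetricSeries(system_label, traj.replica_label, name,
                             np.array(values), times)
            )
    return table, series


def run_analysis(
    config: RunConfig,
    trajectories: dict[str, dict[str, Trajectory]] | None = None,
    params: ParamTable | None = None,
) -> ReportBundle:
    """Run the full per-system analysis and assemble a report bundle.

    ``trajectories`` maps system label → replica label → trajectory; when
    omitted the paths in ``config.trajectories`` are read from disk.
    """
    if trajectories is None:
        if not config.trajectories:
            raise ConfigError("no trajectories configured")
        trajectories = {}
        for system, reps in config.trajectories.items():
            trajectories[system] = {}
            for rep_label, path in reps.items():
                t = read_structure(path)
                t.replica_label = rep_label
                trajectories[system][rep_label] = t
    if params is None and config.params_path:
        params = read_param_table(config.params_path)

    bundle = ReportBundle(
        provenance={
            "config": asdict(config),
            "config_digest": config.digest(),
            "version": __version__,
        }
    )
    for system, reps in trajectories.items():
        replicas = []
        for rep_label, traj in reps.items():
            traj.replica_label = rep_label
            replicas.append(traj)
        table, series = analyze_system(system, replicas, config, params)
        bundle.bond_tables[system] = table
        bundle.metric_series.extend(series)

    for s in {x.system_label for x in bundle.metric_series}:
        for metric in {x.metric_name for x in bundle.metric_series}:
            pooled = np.concatenate(
                [
                    discard_equilibration(x, config.equilibration_fraction).values
                    for x in bundle.metric_series
                    if x.system_label == s and x.metric_name == metric
                ]
            )
            if len(pooled) >= 2 and np.ptp(pooled) > 0:
                bundle.distributions[(s, metric)] = distribution_summary(pooled)

    for sys_a, sys_b in config.comparisons:
        means = {}
        for label in (sys_a, sys_b):
            means[label] = [
                discard_equilibration(x, config.equilibration_fraction).values.mean()
                for x in bundle.metric_series
                if x.system_label == label and x.metric_name == "n_waters"
            ]
        bundle.water_comparisons.append(
            compare_groups(means[sys_a], means[sys_b], sys_a, sys_b)
        )
    return bundle


# ---------------------------------------------------------------------------
# printed-table ingest
# ---------------------------------------------------------------------------

def load_published_ratios() -> pd.DataFrame:
    """Bundled per-replica survival ratios transcribed from published tables."""
    with resources.files("ifacedyn.data").joinpath(
        "published_survival_ratios.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def ingest_printed_table(
    table: pd.DataFrame | str | Path,
    system: str | None = None,
    loop_ranges: dict[str, tuple[int, int]] = DEFAULT_LOOP_RANGES,
) -> list[BondSummary]:
    """Recompute max/ave/std from a table of printed per-replica ratios.

    The table needs ``res_name``/``res_seq``/``atom`` plus partner columns
    and numeric ``equ1..equN`` columns; a ``system`` column allows filtering.
    The table convention lists the antigen atom first, so it is mapped to
    the key's donor slot regardless of chemical role.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    if system is not None:
        if "system" not in table.columns:
            raise ConfigError("table has no 'system' column to filter on")
        table = table[table["system"] == system]
    equ_cols = [c for c in table.columns if c.lower().startswith("equ") and c[3:].isdigit()]
    equ_cols.sort(key=lambda c: int(c[3:]))
    if not equ_cols:
        raise ConfigError("table has no equ1..equN columns")

    records: list[SurvivalRecord] = []
    for _, row in table.iterrows():
        key = HBondKey(
            donor=("P", int(row["res_seq"]), str(row["res_name"]), str(row["atom"])),
            acceptor=(
                str(row.get("partner_chain", "H")),
                int(row["partner_res_seq"]),
                str(row["partner_res_name"]),
                str(row["partner_atom"]),
            ),
        )
        ratios = {}
        for c in equ_cols:
            try:
                ratios[c.capitalize()] = float(row[c])
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"non-numeric ratio {row[c]!r} in column {c}") from exc
        records.append(SurvivalRecord(key, ratios))
    labels = [c.capitalize() for c in equ_cols]
    return summarize_replicas(
        records, replica_labels=labels, loop_ranges=loop_ranges, antigen_chain="P"
    )
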