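"""Scenario configuration: study designs, tissue schedules and cohort simulation.

A scenario file (YAML) declares, per tissue, the observable kinetics the
generative model must reproduce -- the cumulative tagged-fraction targets at
the 8-week analysis age (what the pulse-week experiment reads out), the
recent-division (Ki67-like) time course expressed as per-day division
probabilities, residency cutoffs and loss rates -- plus the pulse design
(labeling kernel, per-tissue tagging efficiency) and the experimental
protocols (pulse weeks, group sizes, analysis ages).

The daily generation influx is *derived*, not stated: expected cohort masses
are linear in the influx, so the weekly neonatal influx levels solve a small
linear system that makes the model's expected tagged fractions match the
declared week-1..6 targets exactly, and the adult influx level is set so the
pool size is stationary between the 8- and 28-week analyses.  This keeps the
fixture in the space of published observables while the simulator remains an
explicit birth/label/division/loss process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .io import validate_cohort
from .simulate import (
    KERNEL_DAYS,
    WEEK_LENGTH,
    PulseDesign,
    TissueSchedule,
    evolve_expectation,
    pulse_for_week,
    simulate_mouse,
    tag_probability,
    trapezoid_kernel,
)

logger = logging.getLogger(__name__)

#: analysis age (days) at which the composition targets are declared
CALIBRATION_DAY = 8 * WEEK_LENGTH
#: age (days) at which the adult influx enforces a stationary pool
ADULT_STATIONARY_DAY = 28 * WEEK_LENGTH
N_TARGET_WEEKS = 6
N_NEONATAL_WEEKS = 8  # weekly influx unknowns: weeks 1..8 of life


def _expand_piecewise(segments: list[list[float]], horizon: int, label: str) -> np.ndarray:
    out = np.full(horizon, np.nan)
    for start, end, value in segments:
        start, end = int(start), int(end)
        if not 0 <= start < end <= horizon:
            raise ConfigurationError(
                f"piecewise segment [{start}, {end}) outside horizon {horizon} in {label}"
            )
        out[start:end] = float(value)
    if np.isnan(out).any():
        raise ConfigurationError(f"piecewise spec {label!r} leaves days uncovered")
    return out


def _weekly_index(day: np.ndarray) -> np.ndarray:
    return day // WEEK_LENGTH  # 0-based week


def calibrate_weekly_influx(
    division: np.ndarray,
    loss_resident: float,
    loss_flux: float,
    residency_cutoff_day: int,
    cumulative_targets: dict[int, float],
    *,
    horizon: int,
    kernel: np.ndarray | None = None,
    calibration_day: int = CALIBRATION_DAY,
    adult_day: int = ADULT_STATIONARY_DAY,
) -> np.ndarray:
    """Solve for the daily influx that reproduces the tagged-fraction targets.

    ``cumulative_targets[w]`` is the expected tagged fraction (at unit
    efficiency) of the ``calibration_day`` pool for a pulse in week ``w``.
    Unknowns are one influx level per week of life 1..8 (weeks 7-8 share the
    unexplained tail equally) plus a constant adult level chosen so the total
    pool mass at ``adult_day`` equals the mass at ``calibration_day``.
    Everything is linear in the influx because cohorts do not interact.
    """
    weeks = sorted(cumulative_targets)
    if weeks != list(range(1, N_TARGET_WEEKS + 1)):
        raise ConfigurationError(
            f"cumulative_targets must cover weeks 1..{N_TARGET_WEEKS}, got {weeks}"
        )
    targets = np.array([cumulative_targets[w] for w in weeks])
    if np.any(np.diff(targets) < 0) or np.any((targets <= 0) | (targets > 1)):
        raise ConfigurationError("cumulative targets must be nondecreasing in (0, 1]")
    kernel = trapezoid_kernel() if kernel is None else np.asarray(kernel, dtype=float)

    probe = TissueSchedule(
        name="probe",
        horizon_days=horizon,
        influx=np.ones(horizon),
        division=division,
        loss_resident=loss_resident,
        loss_flux=loss_flux,
        residency_cutoff_day=residency_cutoff_day,
    )
    # per-birth-day unit masses at the two reference ages
    m_cal = evolve_expectation(probe, None, calibration_day).masses
    m_adult = evolve_expectation(probe, None, adult_day).masses

    n_days = N_NEONATAL_WEEKS * WEEK_LENGTH
    birth_days = np.arange(n_days)
    week_of = _weekly_index(birth_days)  # 0..7
    unit_eff = {"probe": 1.0}

    # pool- and tagged-mass coefficients per weekly influx unknown
    A = np.zeros(N_NEONATAL_WEEKS)
    M = np.zeros((N_TARGET_WEEKS, N_NEONATAL_WEEKS))
    for c in range(N_NEONATAL_WEEKS):
        sel = week_of == c
        A[c] = m_cal[birth_days[sel]].sum()
        for wi, w in enumerate(weeks):
            pulse = pulse_for_week(w, unit_eff, kernel)
            tau = np.array(
                [tag_probability(int(b), pulse, "probe") for b in birth_days[sel]]
            )
            M[wi, c] = float((m_cal[birth_days[sel]] * tau).sum())

    system = np.zeros((N_NEONATAL_WEEKS, N_NEONATAL_WEEKS))
    rhs = np.zeros(N_NEONATAL_WEEKS)
    system[:N_TARGET_WEEKS] = M - targets[:, None] * A[None, :]
    system[N_TARGET_WEEKS] = A  # normalize the calibration-day pool to 1
    rhs[N_TARGET_WEEKS] = 1.0
    # split the post-week-6 tail equally (by final mass) between weeks 7 and 8
    system[N_TARGET_WEEKS + 1, N_NEONATAL_WEEKS - 2] = A[N_NEONATAL_WEEKS - 2]
    system[N_TARGET_WEEKS + 1, N_NEONATAL_WEEKS - 1] = -A[N_NEONATAL_WEEKS - 1]

    levels = np.linalg.solve(system, rhs)
    if np.any(levels < -1e-9):
        raise ConfigurationError(
            "cumulative targets are not reachable with nonnegative influx "
            f"(solved weekly levels {levels})"
        )
    levels = np.clip(levels, 0.0, None)

    influx = np.zeros(horizon)
    influx[:n_days] = levels[week_of]

    # adult influx: stationary pool between calibration_day and adult_day
    remnant = float((influx[:n_days] * m_adult[:n_days]).sum())
    unit_adult = float(m_adult[n_days : adult_day + 1].sum())
    level_adult = (1.0 - remnant) / unit_adult
    if level_adult < 0:
        logger.info(
            "pool grows without adult influx (remnant %.3f); setting adult influx to 0",
            remnant,
        )
        level_adult = 0.0
    influx[n_days:] = level_adult
    return influx


@dataclass(eq=False)
class TissueSpec:
    """Raw per-tissue scenario block plus its calibrated schedule cache."""

    name: str
    raw: dict[str, Any]
    kernel: np.ndarray
    _schedule: TissueSchedule | None = field(default=None, repr=False)

    def build(self) -> TissueSchedule:
        if self._schedule is None:
            horizon = int(self.raw.get("horizon_days", 200))
            division = _expand_piecewise(
                self.raw["division"], horizon, f"{self.name}.division"
            )
            influx = calibrate_weekly_influx(
                division,
                float(self.raw["loss_resident"]),
                float(self.raw["loss_flux"]),
                int(self.raw["residency_cutoff_day"]),
                {int(k): float(v) for k, v in self.raw["cumulative_targets"].items()},
                horizon=horizon,
                kernel=self.kernel,
            )
            self._schedule = TissueSchedule(
                name=self.raw.get("tissue", self.name.split("/")[0]),
                horizon_days=horizon,
                influx=influx,
                division=division,
                loss_resident=float(self.raw["loss_resident"]),
                loss_flux=float(self.raw["loss_flux"]),
                residency_cutoff_day=int(self.raw["residency_cutoff_day"]),
                sampled_cells=int(self.raw.get("sampled_cells", 2000)),
                overdispersion_kappa=float(self.raw.get("overdispersion_kappa", 50.0)),
            )
        return self._schedule


class Scenario:
    """A parsed scenario: pulse design, tissue models and protocols."""

    def __init__(self, config: dict[str, Any], source: str = "<dict>") -> None:
        self.config = config
        self.source = source
        self.name = config.get("name", "scenario")
        self.seed = int(config.get("seed", 0))
        kernel = config.get("pulse", {}).get("kernel")
        self.kernel = trapezoid_kernel() if kernel is None else np.asarray(kernel, float)
        if self.kernel.shape != (KERNEL_DAYS,):
            raise ConfigurationError(f"pulse kernel must have {KERNEL_DAYS} weights")
        self.efficiency: dict[str, float] = {
            t: float(e) for t, e in config.get("pulse", {}).get("efficiency", {}).items()
        }
        self.protocols: dict[str, dict[str, Any]] = config.get("protocols", {})
        self.marker_kappa = float(config.get("marker_kappa", 40.0))

        self._specs: dict[str, TissueSpec] = {}
        for tissue, block in config.get("tissues", {}).items():
            if tissue not in self.efficiency:
                raise ConfigurationError(f"tissue {tissue!r} has no tagging efficiency")
            body = {k: v for k, v in block.items() if k != "subsets"}
            body["tissue"] = tissue
            self._specs[tissue] = TissueSpec(tissue, body, self.kernel)
            for subset, sub_block in (block.get("subsets") or {}).items():
                sub = dict(sub_block)
                sub["tissue"] = tissue
                self._specs[f"{tissue}/{subset}"] = TissueSpec(
                    f"{tissue}/{subset}", sub, self.kernel
                )

    # -- structure ---------------------------------------------------------
    @property
    def tissues(self) -> list[str]:
        return [name for name in self._specs if "/" not in name]

    def subsets(self, tissue: str) -> list[str]:
        prefix = f"{tissue}/"
        return [name[len(prefix):] for name in self._specs if name.startswith(prefix)]

    def markers(self, tissue: str) -> dict[str, dict[str, float]]:
        return self.config["tissues"].get(tissue, {}).get("markers", {}) or {}

    def schedule(self, tissue: str, subset: str | None = None) -> TissueSchedule:
        key = tissue if subset in (None, "all") else f"{tissue}/{subset}"
        if key not in self._specs:
            raise ConfigurationError(f"no schedule defined for {key!r}")
        return self._specs[key].build()

    def pulse(self, week: int | None = None, day: int | None = None) -> PulseDesign:
        if (week is None) == (day is None):
            raise ConfigurationError("specify exactly one of pulse week or pulse day")
        if week is not None:
            return pulse_for_week(week, self.efficiency, self.kernel)
        return PulseDesign(
            first_dose_day=int(day), kernel=self.kernel, efficiency_by_tissue=self.efficiency
        )

    def protocol(self, name: str) -> dict[str, Any]:
        if name not in self.protocols:
            raise ConfigurationError(
                f"unknown protocol {name!r}; available: {sorted(self.protocols)}"
            )
        return self.protocols[name]


def _protocol_pulses(spec: dict[str, Any]) -> list[tuple[int | None, int | None]]:
    """Normalize a protocol block to (pulse_week, pulse_day) pairs."""
    if "pulse_weeks" in spec:
        return [(int(w), None) for w in spec["pulse_weeks"]]
    if "pulse_day" in spec:
        return [(None, int(spec["pulse_day"]))]
    raise ConfigurationError("protocol needs pulse_weeks or pulse_day")


def _protocol_analysis_days(spec: dict[str, Any], pulse_day: int) -> list[int]:
    if "analysis_week" in spec:
        return [int(spec["analysis_week"]) * WEEK_LENGTH]
    if "analysis_weeks" in spec:
        return [int(w) * WEEK_LENGTH for w in spec["analysis_weeks"]]
    if "analysis_days_after" in spec:
        return [pulse_day + int(d) for d in np.atleast_1d(spec["analysis_days_after"])]
    raise ConfigurationError("protocol needs analysis_week(s) or analysis_days_after")


def simulate_cohort(
    scenario: Scenario,
    protocol: str = "ontogeny",
    seed: int | None = None,
    *,
    tissues: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one cohort table under a scenario protocol.

    One row per mouse x tissue (x subset where the protocol includes subset
    stratification).  Deterministic given the seed: the expectation engine
    fixes every group's mean tagged fraction, and mice are drawn in a fixed
    iteration order from a single generator.
    """
    spec = scenario.protocol(protocol)
    if rng is None:
        rng = np.random.default_rng(scenario.seed if seed is None else seed)
    mice = int(spec.get("mice_per_group", 8))
    include_subsets = bool(spec.get("include_subsets", False))
    divided_window = spec.get("divided_window_days")
    tissue_list = tissues if tissues is not None else spec.get("tissues", scenario.tissues)
    for tissue in tissue_list:
        if tissue not in scenario.tissues:
            raise ConfigurationError(f"no schedule defined for requested tissue {tissue!r}")

    records = []
    for tissue in tissue_list:
        strata: list[str | None] = [None]
        if include_subsets:
            strata += scenario.subsets(tissue)
        for subset in strata:
            schedule = scenario.schedule(tissue, subset)
            markers = scenario.markers(tissue) if subset is None else {}
            for week, day in _protocol_pulses(spec):
                pulse = scenario.pulse(week=week, day=day)
                for analysis_day in _protocol_analysis_days(spec, pulse.first_dose_day):
                    state = evolve_expectation(schedule, pulse, analysis_day)
                    for i in range(mice):
                        rec = simulate_mouse(
                            schedule,
                            pulse,
                            analysis_day,
                            rng,
                            mouse_id=(
                                f"{tissue}-{subset or 'all'}-p{pulse.first_dose_day}"
                                f"-a{analysis_day}-m{i + 1:02d}"
                            ),
                            pulse_week=week,
                            state=state,
                            marker_model=markers or None,
                            marker_kappa=scenario.marker_kappa,
                            divided_window_days=divided_window,
                        )
                        rec.subset = subset or "all"
                        row = {
                            "mouse_id": rec.mouse_id,
                            "tissue": rec.tissue,
                            "pulse_week": rec.pulse_week,
                            "pulse_day": rec.pulse_day,
                            "analysis_day": rec.analysis_day,
                            "n_cells": rec.n_cells,
                            "n_tagged": rec.n_tagged,
                            "subset": rec.subset,
                        }
                        if rec.divided_recent is not None:
                            row["divided_recent"] = rec.divided_recent
                        for marker, (tp, tt, up, ut) in rec.marker_counts.items():
                            row[f"{marker}_tag_pos"] = tp
                            row[f"{marker}_tag_tot"] = tt
                            row[f"{marker}_untag_pos"] = up
                            row[f"{marker}_untag_tot"] = ut
                        records.append(row)
    table = pd.DataFrame.from_records(records)
    table = validate_cohort(table)
    table.attrs["scenario"] = scenario.name
    table.attrs["protocol"] = protocol
    table.attrs["seed"] = scenario.seed if seed is None else seed
    return table


def paper_scenario_path() -> Path:
    """Path to the bundled study scenario."""
    return Path(resources.files("tregmap.datasets") / "paper_scenario.yaml")


def load_scenario(path: str | Path | None = None) -> Scenario:
    """Load a scenario YAML; defaults to the bundled study scenario."""
    path = paper_scenario_path() if path is None else Path(path)
    if not path.exists():
        raise ConfigurationError(f"scenario file not found: {path}")
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ConfigurationError(f"scenario file {path} is not a mapping")
    return Scenario(config, source=str(path))
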