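"""Cohort-structured pulse-labeling simulator of tissue Treg pool assembly.

The model works on an integer day grid with day 0 = birth of the mouse and
week ``w`` spanning days ``[7*(w-1), 7*w)``.  Each day ``t`` a tissue receives
``influx[t]`` newly generated Tregs (abstracting thymic output, peripheral
conversion and colonization).  Cells born on day ``b`` form a birth cohort
whose expected mass then evolves multiplicatively: between day ``t`` and
``t+1`` every cell divides with probability ``division[t]`` and is lost with
probability ``loss_resident`` (cohorts born before ``residency_cutoff_day``)
or ``loss_flux`` (cohorts born on/after the cutoff), so the per-day growth
factor is ``1 + division[t] - loss``.

A tamoxifen pulse makes the recombinase active over an 8-day window after the
first dose; the activity time course is the labeling kernel.  A cell present
before the window starts is tagged with the full per-tissue efficiency ``E``;
a cell born on kernel day ``j`` can only be reached by the activity remaining
from day ``j`` onward, so its tag probability is ``E`` times the remaining
kernel mass over the total.  The tag is heritable: division and loss act
identically on tagged and untagged cells of a cohort, so the tagged share of
a cohort is fixed once the window has closed.

``evolve_expectation`` propagates expected (deterministic) cohort masses and
is the oracle against which the stochastic per-mouse sampler
(``simulate_mouse``) is validated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ConfigurationError, ParameterError

logger = logging.getLogger(__name__)

WEEK_LENGTH = 7
#: number of days after the first dose during which recombinase can be active
KERNEL_DAYS = 8


def trapezoid_kernel() -> np.ndarray:
    """Default labeling-activity kernel over days 1..8 after the first dose.

    Full activity on days 1-5, linear decay to zero over days 6-8.  The two
    tamoxifen doses given a few days apart are folded into this single
    envelope.
    """
    return np.array([1.0, 1.0, 1.0, 1.0, 1.0, 2.0 / 3.0, 1.0 / 3.0, 0.0])


@dataclass(frozen=True, eq=False)
class PulseDesign:
    """When labeling starts, its activity kernel and per-tissue efficiency.

    Parameters
    ----------
    first_dose_day : int
        Mouse age in days at the first tamoxifen dose.
    kernel : ndarray, shape (8,)
        Nonnegative activity weights for days 1..8 after the first dose.
        Activity is zero beyond day 8.
    efficiency_by_tissue : mapping
        Tissue name -> tagging efficiency ``E`` in [0, 1], the probability
        that a cell exposed to the full activity window becomes labeled.
    """

    first_dose_day: int
    kernel: np.ndarray = field(default_factory=trapezoid_kernel)
    efficiency_by_tissue: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kernel = np.asarray(self.kernel, dtype=float)
        if kernel.shape != (KERNEL_DAYS,):
            raise ConfigurationError(
                f"kernel must have {KERNEL_DAYS} weights, got shape {kernel.shape}"
            )
        if np.any(kernel < 0) or kernel.sum() <= 0:
            raise ConfigurationError("kernel weights must be nonnegative with a positive sum")
        object.__setattr__(self, "kernel", kernel)
        for tissue, eff in self.efficiency_by_tissue.items():
            if not 0.0 <= eff <= 1.0:
                raise ConfigurationError(f"efficiency for {tissue!r} must be in [0, 1], got {eff}")

    @property
    def window_end_day(self) -> int:
        """First day on which a newborn cell can no longer be labeled."""
        return self.first_dose_day + KERNEL_DAYS + 1

    def efficiency(self, tissue: str) -> float:
        try:
            return float(self.efficiency_by_tissue[tissue])
        except KeyError:
            raise ConfigurationError(
                f"no tagging efficiency configured for tissue {tissue!r}"
            ) from None


def pulse_for_week(
    week: int,
    efficiency_by_tissue: Mapping[str, float],
    kernel: np.ndarray | None = None,
) -> PulseDesign:
    """Pulse design for the 'treated at week w of life' groups.

    The first dose is given on the first full day of week ``w``
    (day ``7*(w-1) + 1``); the second dose three days later is part of the
    same activity envelope.
    """
    if week < 1:
        raise ConfigurationError(f"pulse week must be >= 1, got {week}")
    return PulseDesign(
        first_dose_day=WEEK_LENGTH * (week - 1) + 1,
        kernel=trapezoid_kernel() if kernel is None else kernel,
        efficiency_by_tissue=efficiency_by_tissue,
    )


def tag_probability(
    birth_day: int,
    pulse: PulseDesign,
    tissue: str,
    at_day: int | None = None,
) -> float:
    """Probability that a cell born on ``birth_day`` carries the label.

    Cells present before the activity window starts see the whole kernel and
    are tagged with the full efficiency ``E``.  Cells born on kernel day
    ``j`` (calendar day ``first_dose_day + j``) can only be labeled by the
    remaining activity, so their probability is ``E`` times the kernel mass
    from day ``j`` onward over the total mass.  Cells born after day
    ``first_dose_day + 8`` are never labeled.

    ``at_day`` optionally truncates the kernel to activity elapsed up to that
    analysis day, for observations taken while the window is still open.
    """
    if birth_day < 0:
        raise ParameterError(f"birth_day must be >= 0, got {birth_day}")
    eff = pulse.efficiency(tissue)
    kernel = pulse.kernel
    total = kernel.sum()
    lo = max(1, birth_day - pulse.first_dose_day)  # first kernel day able to reach the cell
    hi = KERNEL_DAYS
    if at_day is not None:
        hi = min(hi, at_day - pulse.first_dose_day)
    if hi < lo:
        return 0.0
    return eff * float(kernel[lo - 1 : hi].sum()) / float(total)


@dataclass(eq=False)
class TissueSchedule:
    """Ground-truth generative model for one tissue.

    Vectors are indexed by day, length ``horizon_days``; day ``t`` values
    drive the transition from day ``t`` to ``t+1``, so analyses are possible
    up to day ``horizon_days - 1``.

    Parameters
    ----------
    influx : ndarray
        Expected number of new Tregs entering the pool on each day.  Units
        are arbitrary (the model works in relative masses).
    division : ndarray
        Per-cell per-day division probability (drives the recent-division
        marker observable as well as cohort growth).
    loss_resident, loss_flux : float
        Per-day loss probabilities for cohorts born before / on-or-after
        ``residency_cutoff_day``.  ``loss_resident > loss_flux``
        (anti-residency) is permitted but logged.
    sampled_cells : int
        Typical number of Tregs acquired by flow cytometry per mouse.
    overdispersion_kappa : float
        Beta concentration for mouse-to-mouse variation of the true tagged
        fraction.
    """

    name: str
    horizon_days: int
    influx: np.ndarray
    division: np.ndarray
    loss_resident: float = 0.0
    loss_flux: float = 0.0
    residency_cutoff_day: int = 0
    sampled_cells: int = 2000
    overdispersion_kappa: float = 50.0

    def __post_init__(self) -> None:
        self.influx = np.asarray(self.influx, dtype=float)
        self.division = np.asarray(self.division, dtype=float)
        for label, vec in (("influx", self.influx), ("division", self.division)):
            if vec.shape != (self.horizon_days,):
                raise ConfigurationError(
                    f"{label} for {self.name!r} must have length horizon_days="
                    f"{self.horizon_days}, got {vec.shape}"
                )
        if np.any(self.influx < 0):
            raise ConfigurationError(f"influx for {self.name!r} must be nonnegative")
        if np.any((self.division < 0) | (self.division >= 1)):
            raise ConfigurationError(f"division for {self.name!r} must lie in [0, 1)")
        for label, delta in (("loss_resident", self.loss_resident), ("loss_flux", self.loss_flux)):
            if not 0.0 <= delta < 1.0:
                raise ConfigurationError(f"{label} for {self.name!r} must lie in [0, 1)")
        if self.residency_cutoff_day < 0:
            raise ConfigurationError("residency_cutoff_day must be >= 0")
        if self.loss_resident > self.loss_flux:
            logger.warning(
                "tissue %r has loss_resident > loss_flux (anti-residency): "
                "cohorts born before day %d are lost faster than later ones",
                self.name,
                self.residency_cutoff_day,
            )
        if self.overdispersion_kappa <= 0:
            raise ConfigurationError("overdispersion_kappa must be > 0")

    def loss_for_birth_day(self, birth_day: int) -> float:
        if birth_day < self.residency_cutoff_day:
            return self.loss_resident
        return self.loss_flux


@dataclass(eq=False)
class CohortState:
    """Expected per-birth-day cohort masses at an analysis day.

    ``masses[b]`` (``labeled[b]``) is the expected total (labeled) cell mass
    of the cohort born on day ``b``.
    """

    analysis_day: int
    masses: np.ndarray
    labeled: np.ndarray
    week_length: int = WEEK_LENGTH

    def __post_init__(self) -> None:
        if np.any(self.masses < -1e-12):
            raise ParameterError("cohort masses must be nonnegative")
        if np.any(self.labeled > self.masses + 1e-9) or np.any(self.labeled < -1e-12):
            raise ParameterError("labeled mass must satisfy 0 <= L <= N")

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def labeled_mass(self) -> float:
        return float(self.labeled.sum())

    @property
    def tagged_fraction(self) -> float:
        total = self.total_mass
        if total <= 0:
            return 0.0
        return self.labeled_mass / total

    def weekly_masses(self) -> np.ndarray:
        """Aggregate per-birth-day masses into birth-week cohorts (week 1 first)."""
        return _weekly_sums(self.masses, self.week_length)

    def weekly_labeled(self) -> np.ndarray:
        return _weekly_sums(self.labeled, self.week_length)


def _weekly_sums(values: np.ndarray, week_length: int) -> np.ndarray:
    n_weeks = math.ceil(len(values) / week_length)
    out = np.zeros(n_weeks)
    for w in range(n_weeks):
        out[w] = values[w * week_length : (w + 1) * week_length].sum()
    return out


def evolve_expectation(
    schedule: TissueSchedule,
    pulse: PulseDesign | None,
    analysis_day: int,
) -> CohortState:
    """Propagate expected cohort masses from day 0 to ``analysis_day``.

    Daily recursion: influx on day ``t`` seeds the cohort born that day, then
    every cohort born on or before ``t`` is multiplied by its growth factor
    ``1 + division[t] - loss``.  Influx arriving on ``analysis_day`` itself is
    not yet part of the measured pool.

    Labeling is heritable and neutral (division and loss are label-blind), so
    the labeled mass of the cohort born on day ``b`` is its total mass times
    ``tag_probability(b, ...)``; for analyses taken before the window closes
    only the activity elapsed by ``analysis_day`` counts.
    """
    if analysis_day >= schedule.horizon_days:
        raise ParameterError(
            f"analysis_day {analysis_day} beyond schedule horizon "
            f"{schedule.horizon_days - 1} for tissue {schedule.name!r}"
        )
    T = analysis_day
    masses = np.zeros(T + 1)
    birth_days = np.arange(T + 1)
    resident = birth_days < schedule.residency_cutoff_day
    rho_for = np.where(resident, -schedule.loss_resident, -schedule.loss_flux)
    for t in range(T):
        masses[t] += schedule.influx[t]
        rho = 1.0 + schedule.division[t] + rho_for[: t + 1]
        if np.any(rho < 0):
            raise ParameterError(
                f"negative growth factor on day {t} for tissue {schedule.name!r}"
            )
        masses[: t + 1] *= rho

    if pulse is None:
        labeled = np.zeros_like(masses)
    else:
        tag = np.array(
            [tag_probability(b, pulse, schedule.name, at_day=T) for b in birth_days]
        )
        labeled = masses * tag
    return CohortState(analysis_day=T, masses=masses, labeled=labeled)


@dataclass(eq=False)
class CompositionTruth:
    """True per-generation-week fractions of an analysis-day pool.

    ``fractions[w-1]`` is the share of the pool descended from cells that
    entered it during week ``w`` of life.  Fractions sum to 1 over all birth
    weeks up to the analysis day.
    """

    fractions: np.ndarray
    analysis_day: int
    week_length: int = WEEK_LENGTH

    def __post_init__(self) -> None:
        if np.any(self.fractions < -1e-12):
            raise ParameterError("composition fractions must be nonnegative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ParameterError("composition fractions must sum to 1")

    @property
    def n_weeks(self) -> int:
        return len(self.fractions)

    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.fractions)

    def fraction_through_week(self, week: int) -> float:
        """Share of the pool generated during weeks 1..week."""
        return float(self.fractions[:week].sum())

    def tail_beyond(self, week: int) -> float:
        """Share of the pool generated after week ``week``."""
        return float(self.fractions[week:].sum())


def true_composition(
    schedule: TissueSchedule,
    analysis_day: int,
    week_length: int = WEEK_LENGTH,
) -> CompositionTruth:
    """Decompose the expected analysis-day pool by birth week."""
    state = evolve_expectation(schedule, None, analysis_day)
    weekly = _weekly_sums(state.masses, week_length)
    total = weekly.sum()
    if total <= 0:
        raise ParameterError("pool is empty at the analysis day")
    return CompositionTruth(
        fractions=weekly / total, analysis_day=analysis_day, week_length=week_length
    )


def divided_recent_fraction(
    schedule: TissueSchedule,
    day: int,
    window_days: int = 4,
) -> float:
    """Expected fraction of pool cells that divided within the trailing window.

    Models a division marker with finite persistence (Ki67-like): a cell is
    positive if it divided during the ``window_days`` daily steps preceding
    ``day``.  A cell born on day ``b`` has only experienced steps from ``b``
    on, so for each birth cohort the positive probability is
    ``1 - prod(1 - division[s])`` over ``s`` in
    ``[max(b, day - window_days), day)``, and cohorts are weighted by their
    expected mass at ``day``.
    """
    if window_days < 1:
        raise ParameterError("window_days must be >= 1")
    state = evolve_expectation(schedule, None, day)
    masses = state.masses
    probs = np.empty_like(masses)
    for b in range(day + 1):
        start = max(b, day - window_days)
        if start >= day:
            probs[b] = 0.0
        else:
            probs[b] = 1.0 - np.prod(1.0 - schedule.division[start:day])
    total = masses.sum()
    if total <= 0:
        return 0.0
    return float((masses * probs).sum() / total)


@dataclass(eq=False)
class MouseRecord:
    """One simulated mouse in one tissue (one row of the cohort table)."""

    mouse_id: str
    tissue: str
    pulse_week: int
    pulse_day: int
    analysis_day: int
    n_cells: int
    n_tagged: int
    subset: str = "all"
    marker_counts: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)
    divided_recent: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_tagged <= self.n_cells:
            raise ParameterError(
                f"n_tagged must satisfy 0 <= n_tagged <= n_cells "
                f"({self.n_tagged} vs {self.n_cells})"
            )
        for marker, (tp, tt, up, ut) in self.marker_counts.items():
            if tp > tt or up > ut or min(tp, tt, up, ut) < 0:
                raise ParameterError(f"inconsistent counts for marker {marker!r}")


def _beta_sample(rng: np.random.Generator, mean: float, kappa: float) -> float:
    """Draw a fraction with the given mean and Beta concentration ``kappa``."""
    if mean <= 0.0:
        return 0.0
    if mean >= 1.0:
        return 1.0
    return float(rng.beta(mean * kappa, (1.0 - mean) * kappa))


def simulate_mouse(
    schedule: TissueSchedule,
    pulse: PulseDesign,
    analysis_day: int,
    rng: np.random.Generator,
    *,
    mouse_id: str = "m0",
    pulse_week: int | None = None,
    state: CohortState | None = None,
    marker_model: Mapping[str, Mapping[str, float]] | None = None,
    marker_kappa: float = 40.0,
    divided_window_days: int | None = None,
) -> MouseRecord:
    """Draw one mouse's flow-cytometry counts around the expectation model.

    The mouse's true tagged fraction is Beta-distributed with mean equal to
    the expectation-model fraction and concentration ``overdispersion_kappa``;
    the observed tagged count is then binomial over ``sampled_cells`` acquired
    cells.  ``state`` may pass a precomputed expectation to avoid re-running
    the engine for every mouse of a group.
    """
    if schedule.sampled_cells <= 0:
        raise ParameterError("sampled_cells must be > 0")
    if state is None:
        state = evolve_expectation(schedule, pulse, analysis_day)
    mean_fraction = state.tagged_fraction
    fraction = _beta_sample(rng, mean_fraction, schedule.overdispersion_kappa)
    n_cells = int(schedule.sampled_cells)
    n_tagged = int(rng.binomial(n_cells, fraction))

    marker_counts: dict[str, tuple[int, int, int, int]] = {}
    if marker_model:
        n_untagged = n_cells - n_tagged
        for marker, props in marker_model.items():
            p_tag = _beta_sample(rng, float(props["tag"]), marker_kappa)
            p_untag = _beta_sample(rng, float(props["untag"]), marker_kappa)
            tag_pos = int(rng.binomial(n_tagged, p_tag)) if n_tagged else 0
            untag_pos = int(rng.binomial(n_untagged, p_untag)) if n_untagged else 0
            marker_counts[marker] = (tag_pos, n_tagged, untag_pos, n_untagged)

    divided: int | None = None
    if divided_window_days is not None:
        p_div = divided_recent_fraction(schedule, analysis_day, divided_window_days)
        divided = int(rng.binomial(n_cells, p_div))

    week = pulse_week if pulse_week is not None else pulse.first_dose_day // WEEK_LENGTH + 1
    return MouseRecord(
        mouse_id=mouse_id,
        tissue=schedule.name,
        pulse_week=week,
        pulse_day=pulse.first_dose_day,
        analysis_day=analysis_day,
        n_cells=n_cells,
        n_tagged=n_tagged,
        marker_counts=marker_counts,
        divided_recent=divided,
    )
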