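"""Renewal and residency kinetics from labeled-fraction time courses.

After an adult pulse the tagged fraction of a tissue's Treg pool decays as
unlabeled newcomers replace labeled cells.  The working model is exponential
decay towards a plateau of non-replaced resident cells,

    F(t) = plateau + (F0 - plateau) * exp(-r * (t - t1)),

with time in weeks, ``F0`` the fraction at the first timepoint, ``r >= 0``
the replacement rate per week and half-life ``ln 2 / r``.  Two-point
replacement rates and persistence ratios cover the designs where only two
ages were sampled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import FitError, ParameterError

logger = logging.getLogger(__name__)


def two_point_rate(F1: float, t1: float, F2: float, t2: float) -> tuple[float, float]:
    """Replacement rate (per week) and half-life from two labeled fractions.

    Assumes plateau-free exponential decay between the two ages, so
    ``r = ln(F1/F2) / (t2 - t1)``.  Times are in weeks.
    """
    if not 0 < F2 <= F1 <= 1:
        raise ParameterError(
            "label gain is unphysical; check inputs (need 0 < F2 <= F1 <= 1, "
            f"got F1={F1}, F2={F2})"
        )
    if t2 <= t1:
        raise ParameterError("t2 must be later than t1")
    rate = math.log(F1 / F2) / (t2 - t1)
    half_life = math.inf if rate == 0 else math.log(2) / rate
    return rate, half_life


def persistence_ratio(F_later: float, F_earlier: float) -> float:
    """Fraction of labeled cells persisting between two observations.

    Interpreted as the persisting share under a constant-pool assumption:
    if the pool size is stable, the ratio of tagged fractions equals the
    ratio of tagged cell numbers.  That assumption is logged with every call
    because pool growth inflates apparent replacement.
    """
    if F_earlier <= 0:
        raise ParameterError("F_earlier must be > 0")
    logger.info(
        "persistence_ratio assumes a constant pool size between the two observations"
    )
    ratio = F_later / F_earlier
    if ratio > 1:
        logger.warning(
            "persistence ratio %.3f > 1: label fraction increased over time "
            "(pool shrinkage or sampling noise)",
            ratio,
        )
    return ratio


@dataclass(eq=False)
class DecayResults:
    """Fitted exponential-with-plateau label decay.

    Attributes
    ----------
    F0 : fraction at the first timepoint.
    plateau : non-replaced resident fraction (0 when the plateau is fixed).
    rate_per_week : replacement rate ``r``.
    half_life_weeks : ``ln 2 / r`` (inf when ``r`` is 0).
    """

    model: "LabelDecayModel"
    F0: float
    plateau: float
    rate_per_week: float
    residuals: np.ndarray
    sse: float
    free_plateau: bool

    @property
    def half_life_weeks(self) -> float:
        if self.rate_per_week <= 0:
            return math.inf
        return math.log(2) / self.rate_per_week

    @property
    def n_points(self) -> int:
        return len(self.model.times)

    def predict(self, times_weeks: np.ndarray) -> np.ndarray:
        t = np.asarray(times_weeks, dtype=float)
        return _decay_curve(t, self.model.times[0], self.F0, self.plateau, self.rate_per_week)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tissue": [self.model.label],
                "F0": [self.F0],
                "plateau": [self.plateau],
                "rate_per_week": [self.rate_per_week],
                "half_life_weeks": [self.half_life_weeks],
                "n_points": [self.n_points],
            }
        )

    def summary(self) -> str:
        hl = self.half_life_weeks
        return "\n".join(
            [
                f"Label-decay fit -- {self.model.label} "
                f"({'free' if self.free_plateau else 'fixed-zero'} plateau, "
                f"{self.n_points} timepoints)",
                f"  F0            : {self.F0:.4f}",
                f"  plateau       : {self.plateau:.4f}",
                f"  rate (per wk) : {self.rate_per_week:.5f}",
                f"  half-life (wk): {'inf' if math.isinf(hl) else f'{hl:.2f}'}",
                f"  SSE           : {self.sse:.3e}",
            ]
        )


def _decay_curve(t: np.ndarray, t0: float, F0: float, plateau: float, rate: float) -> np.ndarray:
    return plateau + (F0 - plateau) * np.exp(-rate * (t - t0))


class LabelDecayModel:
    """Least-squares model for tagged-fraction decay over age.

    Parameters
    ----------
    times_weeks : array
        Analysis ages in weeks, strictly increasing.
    fractions : array
        Tagged fractions at those ages (group medians by default when built
        via :meth:`from_cohort`).
    weights : array, optional
        Per-point weights (e.g. mice per group) for a weighted fit.
    label : str
        Name used in summaries (typically the tissue).
    """

    def __init__(
        self,
        times_weeks: np.ndarray,
        fractions: np.ndarray,
        weights: np.ndarray | None = None,
        label: str = "pool",
    ) -> None:
        self.times = np.asarray(times_weeks, dtype=float)
        self.fractions = np.asarray(fractions, dtype=float)
        self.label = label
        if self.times.ndim != 1 or self.times.shape != self.fractions.shape:
            raise ParameterError("times and fractions must be equal-length 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ParameterError("fractions must lie in [0, 1]")
        self.weights = (
            np.ones_like(self.fractions) if weights is None else np.asarray(weights, dtype=float)
        )
        if np.any(self.weights <= 0):
            raise ParameterError("weights must be positive")

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        tissue: str,
        *,
        subset: str | None = None,
        stat: str = "median",
        per_mouse: bool = False,
        week_length: int = 7,
    ) -> "LabelDecayModel":
        """Build the decay series from a cohort table (one pulse group).

        Group medians per analysis age by default; ``per_mouse=True`` fits all
        mouse-level points weighted equally instead.
        """
        rows = cohort[cohort["tissue"] == tissue]
        if "subset" in cohort.columns:
            rows = rows[rows["subset"] == (subset or "all")]
        if rows.empty:
            raise ParameterError(f"no records for tissue {tissue!r}")
        if rows["pulse_day"].nunique() > 1:
            raise ParameterError(
                "decay fits need a single pulse group; filter the cohort first"
            )
        fractions = rows["n_tagged"] / rows["n_cells"]
        t_weeks = rows["analysis_day"] / week_length
        if per_mouse:
            order = np.argsort(t_weeks.to_numpy(), kind="stable")
            # jitter-free strictly increasing times are not guaranteed per mouse;
            # collapse exact duplicates is not needed for least squares
            model = cls.__new__(cls)
            model.times = t_weeks.to_numpy()[order]
            model.fractions = fractions.to_numpy()[order]
            model.weights = np.ones(len(order))
            model.label = tissue
            return model
        grouped = (
            pd.DataFrame({"t": t_weeks, "f": fractions})
            .groupby("t")["f"]
            .agg("median" if stat == "median" else "mean")
        )
        counts = pd.DataFrame({"t": t_weeks}).groupby("t").size()
        return cls(
            grouped.index.to_numpy(),
            grouped.to_numpy(),
            weights=counts.to_numpy(dtype=float),
            label=tissue if subset is None else f"{tissue}/{subset}",
        )

    def fit(self, free_plateau: bool = True) -> DecayResults:
        """Box-constrained least squares with five deterministic starts.

        Parameters are ``(F0, s, r)`` with ``plateau = s * F0`` so the
        constraint ``0 <= plateau <= F0 <= 1`` is built in; ``r >= 0``.
        The best of the five starts by SSE is kept.
        """
        n_min = 3 if free_plateau else 2
        if len(self.times) < n_min:
            raise ParameterError(
                f"need >= {n_min} timepoints for a {'free' if free_plateau else 'fixed'}-"
                "plateau fit"
            )
        t0 = self.times[0]
        f_first, f_last = self.fractions[0], self.fractions[-1]
        span = self.times[-1] - self.times[0]
        w = np.sqrt(self.weights)

        # deterministic multi-start grid for the rate (per week)
        r_guesses = [0.0, 0.05, 0.2, 1.0]
        if 0 < f_last < f_first:
            r_guesses.append(math.log(f_first / f_last) / span)
        starts = []
        for i, r0 in enumerate(r_guesses[:5]):
            s0 = 0.0 if not free_plateau else (0.0 if i % 2 == 0 else min(1.0, f_last / max(f_first, 1e-9)))
            starts.append((max(f_first, 1e-6), s0, r0))

        def residual(theta: np.ndarray) -> np.ndarray:
            F0, s, r = theta
            plateau = s * F0 if free_plateau else 0.0
            return w * (_decay_curve(self.times, t0, F0, plateau, r) - self.fractions)

        best = None
        for F0_0, s0, r0 in starts:
            try:
                res = least_squares(
                    residual,
                    x0=[F0_0, s0, max(r0, 0.0)],
                    bounds=([0.0, 0.0, 0.0], [1.0, 1.0, 50.0]),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:  # pragma: no cover - scipy failures surface below
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitError(
                f"label-decay fit failed to converge for {self.label!r} "
                f"(n={len(self.times)}, fractions={self.fractions})"
            )
        F0, s, rate = best.x
        plateau = s * F0 if free_plateau else 0.0
        if rate < 1e-6:
            # no measurable replacement: the curve is flat at F0
            rate = 0.0
            plateau = F0
        residuals = _decay_curve(self.times, t0, F0, plateau, rate) - self.fractions
        return DecayResults(
            model=self,
            F0=float(F0),
            plateau=float(plateau),
            rate_per_week=float(rate),
            residuals=residuals,
            sse=float(np.sum(self.weights * residuals**2)),
            free_plateau=free_plateau,
        )
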