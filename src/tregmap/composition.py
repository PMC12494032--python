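"""Retrospective decomposition of an adult Treg pool by generation week.

A pulse given in week ``w`` labels every Treg generated up to the end of its
activity window, so the tagged fraction measured at the common analysis age
is a *cumulative* readout: cells generated during weeks ``1..w``.  The
pipeline estimates the pool composition from a cohort table by

1. summarizing per-mouse tagged fractions per pulse-week group (median by
   default, matching how group values are reported),
2. dividing by the per-tissue tagging efficiency (clamped at 1),
3. projecting onto nondecreasing cumulative values (weighted least squares
   via pool-adjacent-violators) -- sampling noise must not produce negative
   "generated during week w" increments,
4. differencing successive cumulative values into per-week increments plus a
   "generated later" tail.

Uncertainty comes from a within-group mouse bootstrap; the 10x10 waffle view
uses largest-remainder (Hamilton) apportionment of 100 grid cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression

from .exceptions import ParameterError, ValidationError

logger = logging.getLogger(__name__)

TAIL_LABEL = ">{last_week}"


@dataclass(eq=False)
class GroupSummary:
    """Tagged-fraction summary of one pulse-week group in one tissue."""

    pulse_week: int
    tissue: str
    fraction: float
    n_mice: int
    mouse_fractions: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ParameterError(f"group fraction must be in [0, 1], got {self.fraction}")


def summarize_groups(
    cohort: pd.DataFrame,
    tissue: str,
    *,
    subset: str | None = None,
    pulse_weeks: list[int] | None = None,
    stat: str = "median",
) -> list[GroupSummary]:
    """Per-pulse-week tagged-fraction summaries for one tissue.

    Per-mouse fraction is ``n_tagged / n_cells``; the group summary is the
    median across mice (the convention used for group bars), or the mean with
    ``stat="mean"``.
    """
    if stat not in ("median", "mean"):
        raise ParameterError(f"stat must be 'median' or 'mean', got {stat!r}")
    rows = cohort[cohort["tissue"] == tissue]
    if subset is not None and "subset" in cohort.columns:
        rows = rows[rows["subset"] == subset]
    elif "subset" in cohort.columns:
        rows = rows[rows["subset"] == "all"]
    if rows.empty:
        raise ValidationError(
            f"no records for tissue {tissue!r}"
            + (f" subset {subset!r}" if subset is not None else "")
        )
    weeks = sorted(rows["pulse_week"].unique()) if pulse_weeks is None else list(pulse_weeks)
    missing = [w for w in weeks if not (rows["pulse_week"] == w).any()]
    if missing:
        raise ValidationError(
            f"tissue {tissue!r} has no mice for pulse weeks {missing}"
        )
    out = []
    for week in weeks:
        grp = rows[rows["pulse_week"] == week]
        fractions = (grp["n_tagged"] / grp["n_cells"]).to_numpy(dtype=float)
        value = float(np.median(fractions) if stat == "median" else np.mean(fractions))
        out.append(
            GroupSummary(
                pulse_week=int(week),
                tissue=tissue,
                fraction=value,
                n_mice=len(fractions),
                mouse_fractions=fractions,
            )
        )
    return out


def correct_efficiency(fraction: float, efficiency: float) -> float:
    """Rescale a measured tagged fraction by the tagging efficiency.

    The fate-mapping system only tags a fraction ``E`` of eligible cells, so
    the measured tagged fraction underestimates the generated share by that
    factor.  The corrected value is clamped at 1.
    """
    if efficiency <= 0:
        raise ParameterError(f"efficiency must be > 0, got {efficiency}")
    if fraction < 0:
        raise ParameterError(f"fraction must be >= 0, got {fraction}")
    return min(fraction / efficiency, 1.0)


def isotonic_nondecreasing(
    values: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Weighted least-squares nondecreasing fit (pool-adjacent-violators)."""
    values = np.asarray(values, dtype=float)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != values.shape:
            raise ParameterError("values and weights must have equal length")
        if np.any(weights <= 0):
            raise ParameterError("weights must be positive")
    res = isotonic_regression(values, weights=weights, increasing=True)
    return np.asarray(res.x, dtype=float)


def decompose(cumulative: np.ndarray, *, atol: float = 1e-9) -> tuple[np.ndarray, float]:
    """Difference corrected, monotone cumulative fractions into increments.

    ``cumulative[w-1]`` is the estimated fraction of the pool generated during
    weeks ``1..w``.  Returns per-week increments and the "generated later"
    tail ``1 - cumulative[-1]``.
    """
    cumulative = np.asarray(cumulative, dtype=float)
    if np.any(np.diff(cumulative) < -atol):
        raise ParameterError(
            "cumulative fractions must be nondecreasing; run isotonic_nondecreasing first"
        )
    if np.any(cumulative < -atol) or np.any(cumulative > 1 + atol):
        raise ParameterError("cumulative fractions must lie in [0, 1]")
    increments = np.diff(np.concatenate([[0.0], cumulative]))
    increments = np.clip(increments, 0.0, None)
    tail = max(0.0, 1.0 - float(cumulative[-1]))
    return increments, tail


def waffle_allocate(fractions: np.ndarray, cells: int = 100) -> np.ndarray:
    """Largest-remainder (Hamilton) apportionment of grid cells to fractions.

    Ties in the fractional remainders are broken in favour of the earlier
    entry (earlier generation week).
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0):
        raise ParameterError("fractions must be nonnegative")
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise ParameterError(f"fractions must sum to 1, got {fractions.sum():.8f}")
    quotas = fractions * cells
    allocation = np.floor(quotas).astype(int)
    remainders = quotas - allocation
    short = cells - int(allocation.sum())
    # stable sort on descending remainder; earlier index wins ties
    order = sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        allocation[i] += 1
    return allocation


def waffle_text(allocation: np.ndarray, labels: list[str], *, width: int = 10) -> str:
    """Render a Hamilton allocation as a text waffle grid (row-major fill)."""
    symbols = "123456789abcdefghijk"
    cells: list[str] = []
    for idx, count in enumerate(allocation):
        cells.extend(symbols[idx % len(symbols)] * int(count))
    lines = ["".join(cells[r * width : (r + 1) * width]) for r in range(len(cells) // width)]
    legend = ", ".join(
        f"{symbols[i % len(symbols)]}={labels[i]} ({allocation[i]})" for i in range(len(labels))
    )
    return "\n".join(lines + [legend])


class PoolCompositionModel:
    """Estimate the generation-week composition of a tissue Treg pool.

    Statsmodels-style model object: construct from a cohort table, call
    :meth:`fit` to obtain a :class:`CompositionResults`.

    Parameters
    ----------
    cohort : DataFrame
        Cohort table (see :func:`tregmap.io.read_cohort`).
    tissue : str
        Tissue to analyse.
    efficiency : float or mapping
        Per-tissue tagging efficiency; a mapping is indexed by tissue name.
    subset : str, optional
        Restrict the analysis to a transcription-factor subset (rows whose
        ``subset`` column matches); the untouched pipeline then estimates the
        subset's own generation kinetics.
    pulse_weeks : list of int, optional
        Pulse-week groups to use; defaults to all groups present.
    stat : {"median", "mean"}
        Group summary statistic.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        tissue: str,
        efficiency: float | dict[str, float] = 1.0,
        *,
        subset: str | None = None,
        pulse_weeks: list[int] | None = None,
        stat: str = "median",
    ) -> None:
        self.cohort = cohort
        self.tissue = tissue
        self.subset = subset
        self.stat = stat
        if isinstance(efficiency, dict):
            if tissue not in efficiency:
                raise ParameterError(f"no efficiency entry for tissue {tissue!r}")
            self.efficiency = float(efficiency[tissue])
        else:
            self.efficiency = float(efficiency)
        if not 0 < self.efficiency <= 1:
            raise ParameterError(f"efficiency must be in (0, 1], got {self.efficiency}")
        self.groups = summarize_groups(
            cohort, tissue, subset=subset, pulse_weeks=pulse_weeks, stat=stat
        )
        self.pulse_weeks = [g.pulse_week for g in self.groups]
        for g in self.groups:
            if g.n_mice == 1:
                logger.warning(
                    "pulse week %d in tissue %r has a single mouse; "
                    "bootstrap intervals will be degenerate",
                    g.pulse_week,
                    tissue,
                )

    # -- internal pipeline ------------------------------------------------
    def _estimate(self, fractions: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        corrected = np.array([correct_efficiency(f, self.efficiency) for f in fractions])
        monotone = np.clip(isotonic_nondecreasing(corrected, weights), 0.0, 1.0)
        increments, tail = decompose(monotone)
        return monotone, increments, tail

    def fit(
        self,
        bootstrap: int = 1000,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> "CompositionResults":
        """Run the decomposition pipeline, optionally with bootstrap CIs.

        ``bootstrap=0`` skips interval estimation.  Bootstrap resamples mice
        with replacement within each pulse-week group and reruns the whole
        summarize -> correct -> isotonic -> difference pipeline.
        """
        weights = np.array([g.n_mice for g in self.groups], dtype=float)
        point = np.array([g.fraction for g in self.groups])
        monotone, increments, tail = self._estimate(point, weights)

        ci = None
        if bootstrap:
            if bootstrap < 100:
                raise ParameterError("bootstrap must be 0 or >= 100 replicates")
            rng = np.random.default_rng(seed)
            n_weeks = len(self.groups)
            boot = np.empty((bootstrap, n_weeks + 1))
            # vectorized within-group resampling of per-mouse fractions
            resampled = np.empty((bootstrap, n_weeks))
            for j, g in enumerate(self.groups):
                idx = rng.integers(0, g.n_mice, size=(bootstrap, g.n_mice))
                draws = g.mouse_fractions[idx]
                resampled[:, j] = (
                    np.median(draws, axis=1) if self.stat == "median" else draws.mean(axis=1)
                )
            for b in range(bootstrap):
                _, inc_b, tail_b = self._estimate(resampled[b], weights)
                boot[b, :n_weeks] = inc_b
                boot[b, n_weeks] = tail_b
            lo = np.quantile(boot, alpha / 2, axis=0)
            hi = np.quantile(boot, 1 - alpha / 2, axis=0)
            ci = np.column_stack([lo, hi])

        return CompositionResults(
            model=self,
            cumulative=monotone,
            increments=increments,
            tail=tail,
            conf_int_=ci,
            n_bootstrap=bootstrap,
            alpha=alpha,
            seed=seed,
        )


@dataclass(eq=False)
class CompositionResults:
    """Estimated composition of the analysis-age pool by generation week.

    ``increments[w]`` is the estimated fraction of the pool generated during
    pulse week ``pulse_weeks[w]``; ``tail`` is the fraction generated after
    the last pulse week.  Both live on [0, 1] and sum to 1.
    """

    model: PoolCompositionModel
    cumulative: np.ndarray
    increments: np.ndarray
    tail: float
    conf_int_: np.ndarray | None
    n_bootstrap: int
    alpha: float
    seed: int | None = None

    @property
    def pulse_weeks(self) -> list[int]:
        return self.model.pulse_weeks

    @property
    def tissue(self) -> str:
        return self.model.tissue

    def fraction_through_week(self, week: int) -> float:
        """Estimated fraction of the pool generated during weeks 1..week."""
        weeks = self.pulse_weeks
        if week not in weeks:
            raise ParameterError(f"no pulse group for week {week}; have {weeks}")
        return float(self.cumulative[weeks.index(week)])

    def conf_int(self) -> pd.DataFrame:
        if self.conf_int_ is None:
            raise ParameterError("fit with bootstrap > 0 to obtain confidence intervals")
        labels = [str(w) for w in self.pulse_weeks] + [f">{self.pulse_weeks[-1]}"]
        return pd.DataFrame(self.conf_int_, index=labels, columns=["ci_lo", "ci_hi"])

    def waffle(self, cells: int = 100) -> np.ndarray:
        """Hamilton allocation of the composition onto ``cells`` grid units."""
        fractions = np.concatenate([self.increments, [self.tail]])
        total = fractions.sum()
        if total <= 0:
            raise ParameterError("empty composition")
        return waffle_allocate(fractions / total, cells)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per generation week plus the tail row."""
        labels = [str(w) for w in self.pulse_weeks] + [f">{self.pulse_weeks[-1]}"]
        increments = np.concatenate([self.increments, [self.tail]])
        cumulative = np.concatenate([self.cumulative, [1.0]])
        if self.conf_int_ is not None:
            lo, hi = self.conf_int_[:, 0], self.conf_int_[:, 1]
        else:
            lo = hi = np.full(len(labels), np.nan)
        return pd.DataFrame(
            {
                "tissue": self.tissue,
                "subset": self.model.subset or "all",
                "week": labels,
                "increment": increments,
                "ci_lo": lo,
                "ci_hi": hi,
                "cumulative_corrected": cumulative,
            }
        )

    def summary(self) -> str:
        lines = [
            f"Treg pool composition by generation week -- tissue: {self.tissue}"
            + (f" / subset: {self.model.subset}" if self.model.subset else ""),
            f"group statistic: {self.model.stat}; efficiency: {self.model.efficiency:.3f}; "
            f"bootstrap: {self.n_bootstrap}",
            f"{'week':>6} {'increment':>10} {'cumulative':>11}"
            + ("  [{:.0f}% CI]".format((1 - self.alpha) * 100) if self.conf_int_ is not None else ""),
        ]
        frame = self.to_frame()
        for _, row in frame.iterrows():
            line = f"{row['week']:>6} {row['increment']:>10.3f} {row['cumulative_corrected']:>11.3f}"
            if self.conf_int_ is not None:
                line += f"  [{row['ci_lo']:.3f}, {row['ci_hi']:.3f}]"
            lines.append(line)
        return "\n".join(lines)


def bootstrap_composition(
    cohort: pd.DataFrame,
    tissue: str,
    efficiency: float | dict[str, float],
    n_bootstrap: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for per-week increments (convenience wrapper)."""
    model = PoolCompositionModel(cohort, tissue, efficiency, **kwargs)
    return model.fit(bootstrap=n_bootstrap, seed=seed).conf_int()


def stratified_reconstruct(
    cohort: pd.DataFrame,
    tissue: str,
    subsets: list[str],
    efficiency: float | dict[str, float] = 1.0,
    *,
    bootstrap: int = 0,
    seed: int | None = None,
    **kwargs,
) -> dict[str, CompositionResults]:
    """Run the composition pipeline on each transcription-factor subset.

    Subsets with no rows in the given tissue (e.g. RORgt+ cells outside the
    colon) are skipped with a log message rather than raising.
    """
    results: dict[str, CompositionResults] = {}
    available = (
        set(cohort.loc[cohort["tissue"] == tissue, "subset"].unique())
        if "subset" in cohort.columns
        else set()
    )
    for subset in subsets:
        if subset not in available:
            logger.info(
                "subset %r absent in tissue %r; skipping stratified reconstruction",
                subset,
                tissue,
            )
            continue
        model = PoolCompositionModel(cohort, tissue, efficiency, subset=subset, **kwargs)
        results[subset] = model.fit(bootstrap=bootstrap, seed=seed)
    return results
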