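"""Paired marker statistics for tagged versus untagged Tregs.

Both arms of every comparison come from the same mouse (tagged and untagged
cells of one sample), so the default test is the Wilcoxon signed-rank test on
the paired per-mouse differences, with the exact null distribution for small
samples.  The exact tail is computed by dynamic programming over the signed
rank sums, which also handles midranks from tied absolute differences; a
normal approximation with continuity correction takes over for n > 25.
Multi-marker reports control the false discovery rate by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError, ValidationError

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25


def _exact_signed_rank_sf(ranks2: np.ndarray, w2: int) -> float:
    """P(W+ >= w) under the exact signed-rank null, ranks doubled to integers.

    ``ranks2`` are the (mid)ranks multiplied by 2 so ties yield integers; the
    null assigns each rank to the positive sum independently with probability
    1/2.  Counts configurations by convolution.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= 2.0 ** len(ranks2)
    return float(counts[w2:].sum())


def paired_marker_test(
    tag_fractions: Iterable[float],
    untag_fractions: Iterable[float],
    *,
    zero_method: str = "wilcox",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired tagged/untagged marker fractions.

    Returns ``(W+, p)`` where ``W+`` is the positive-rank sum of the
    differences ``tag - untag``.  Zero differences are discarded by default
    (``zero_method="wilcox"``); ``"pratt"`` keeps them in the ranking but
    drops their ranks from both sums.  The null distribution is exact for
    n <= 25 retained pairs, a continuity-corrected normal approximation
    above.  If every difference is zero the test is uninformative and returns
    p = 1 with a warning.
    """
    tag = np.asarray(list(tag_fractions), dtype=float)
    untag = np.asarray(list(untag_fractions), dtype=float)
    if tag.shape != untag.shape or tag.ndim != 1:
        raise ParameterError("tag and untag fractions must be equal-length 1-D vectors")
    # round to stabilise ties: float subtraction of equal magnitudes must not
    # split midranks (0.6 - 0.5 != 0.1 exactly)
    diffs = np.round(tag - untag, 12)
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; test is uninformative", stacklevel=2)
        return 0.0, 1.0
    if zero_method == "wilcox":
        diffs = diffs[diffs != 0]
        ranks = stats.rankdata(np.abs(diffs))
    elif zero_method == "pratt":
        ranks_all = stats.rankdata(np.abs(diffs))
        keep = diffs != 0
        ranks = ranks_all[keep]
        diffs = diffs[keep]
    else:
        raise ParameterError(f"zero_method must be 'wilcox' or 'pratt', got {zero_method!r}")
    n = len(diffs)
    if n < 2:
        raise ParameterError("need >= 2 nonzero paired differences")

    w_plus = float(ranks[diffs > 0].sum())
    total = float(ranks.sum())
    if n <= EXACT_N_MAX:
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        sf = _exact_signed_rank_sf(ranks2, w2)  # P(W+ >= observed)
        # null is symmetric around total/2: P(W+ <= w) = P(W+ >= total - w)
        cdf = _exact_signed_rank_sf(ranks2, int(round(2 * (total - w_plus))))
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(sf, cdf))
    else:
        mean = total / 2.0
        # tie-corrected variance of the signed rank sum
        var = float(np.sum(ranks**2)) / 4.0
        z_num = w_plus - mean
        cc = 0.5 * np.sign(z_num)
        z = (z_num - cc) / np.sqrt(var)
        if alternative == "greater":
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
        p = min(1.0, p)
    return w_plus, p


def rank_sum_test(
    tag_fractions: Iterable[float], untag_fractions: Iterable[float]
) -> tuple[float, float]:
    """Unpaired Mann-Whitney/Wilcoxon rank-sum alternative (exact for small n)."""
    res = stats.mannwhitneyu(
        list(tag_fractions), list(untag_fractions), alternative="two-sided"
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marker_columns(cohort: pd.DataFrame) -> list[str]:
    """Marker names encoded in the cohort table's optional count columns."""
    names = []
    for col in cohort.columns:
        if col.endswith("_tag_pos"):
            marker = col[: -len("_tag_pos")]
            quad = [f"{marker}_{suffix}" for suffix in ("tag_pos", "tag_tot", "untag_pos", "untag_tot")]
            if all(c in cohort.columns for c in quad):
                names.append(marker)
    return names


def marker_fractions(
    cohort: pd.DataFrame, tissue: str, marker: str, *, subset: str = "all"
) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-mouse positive fractions among tagged and untagged Tregs."""
    rows = cohort[cohort["tissue"] == tissue]
    if "subset" in cohort.columns:
        rows = rows[rows["subset"] == subset]
    quad = [f"{marker}_{suffix}" for suffix in ("tag_pos", "tag_tot", "untag_pos", "untag_tot")]
    missing = [c for c in quad if c not in rows.columns]
    if missing:
        raise ValidationError(f"marker {marker!r} missing columns {missing}")
    rows = rows.dropna(subset=quad)
    rows = rows[(rows[quad[1]] > 0) & (rows[quad[3]] > 0)]
    tag = (rows[quad[0]] / rows[quad[1]]).to_numpy(dtype=float)
    untag = (rows[quad[2]] / rows[quad[3]]).to_numpy(dtype=float)
    return tag, untag


def marker_report(
    cohort: pd.DataFrame,
    tissue: str,
    markers: list[str] | None = None,
    *,
    subset: str = "all",
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """Per-marker tagged-vs-untagged comparison table for one tissue.

    Columns: marker, n (paired mice), median positive fraction among tagged
    and untagged cells, their difference, raw Wilcoxon p and BH-adjusted q.
    Ordered by decreasing ``|delta|``.  Markers whose counts are missing in
    the tissue are skipped with a log message.
    """
    if markers is None:
        markers = marker_columns(cohort)
    records = []
    for marker in markers:
        try:
            tag, untag = marker_fractions(cohort, tissue, marker, subset=subset)
        except ValidationError:
            logger.info("marker %r has no counts in tissue %r; skipped", marker, tissue)
            continue
        if len(tag) < 2:
            logger.info(
                "marker %r has fewer than 2 paired mice in tissue %r; skipped",
                marker,
                tissue,
            )
            continue
        stat, p = paired_marker_test(tag, untag, zero_method=zero_method)
        records.append(
            {
                "tissue": tissue,
                "marker": marker,
                "n": len(tag),
                "median_tag": float(np.median(tag)),
                "median_untag": float(np.median(untag)),
                "delta": float(np.median(tag) - np.median(untag)),
                "statistic": stat,
                "p_value": p,
            }
        )
    if not records:
        raise ValidationError(f"no usable markers for tissue {tissue!r}")
    report = pd.DataFrame.from_records(records)
    report["q_value"] = bh_adjust(report["p_value"].to_numpy())
    report = report.reindex(
        report["delta"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)
    return report
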