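"""Non-parametric comparison of conditions and plate-level robust scoring.

Migration parameter distributions are typically right-skewed and
non-Gaussian, so pairwise condition comparisons use the Mann-Whitney U
test rather than a t-test. Tests run on trajectory-centric values by
default — one value per track — which avoids the pseudo-replication that
pooled steps would introduce (steps of one cell are strongly correlated);
step-centric testing is available behind a flag for exploratory use.

Testing every pair of k conditions performs k(k−1)/2 hypotheses, so the
raw p-values can be corrected with Bonferroni or Benjamini-Hochberg
(the default) over the full pair set.

For plate-level quality control, each well's summary metric is scored
with the robust z*-score used in high-throughput screening:

    z*_j = (x_j − median(x)) / (1.4826 · MAD(x))

with median and MAD taken over all data-bearing wells of the plate. The
1.4826 factor makes the MAD a consistent estimator of the standard
deviation under normality, so |z*| reads like an ordinary z-score while
staying insensitive to outlier wells.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .migration_parameters import collect_distribution, summarize_track
from .track_io import Experiment

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "adjust_pvalues",
    "pairwise_comparison_table",
    "comparison_matrix",
    "robust_zscore",
    "plate_scores",
    "CORRECTIONS",
    "PLATE_METRICS",
]

CORRECTIONS = ("none", "bonferroni", "benjamini_hochberg")
PLATE_METRICS = ("n_tracks", "mean_speed", "median_speed",
                 "mean_directionality", "median_directionality", "robust_z")

# exact enumeration is cheap and tie-free below this sample size
_EXACT_MAX_N = 8


def mann_whitney_u(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample_a, p).

    ``mode='exact'`` enumerates the null distribution of U (only valid
    without ties); ``'normal_approx'`` uses the tie-corrected normal
    approximation with continuity correction; ``'auto'`` picks exact when
    the smaller sample has ≤ 8 observations and the pooled data are
    tie-free. Two identical constant samples are maximally unseparated and
    give p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2.0
        return u, 1.0
    if mode == "auto":
        mode = "exact" if (min(len(a), len(b)) <= _EXACT_MAX_N and not has_ties) \
            else "normal_approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact Mann-Whitney p is undefined with ties")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "normal_approx":
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    else:
        raise ValueError("mode must be 'exact', 'normal_approx' or 'auto'")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def adjust_pvalues(p_list: Sequence[float], method: str) -> np.ndarray:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m·p). ``benjamini_hochberg``: step-up adjusted
    values, monotone in the p ordering, capped at 1. ``none``: unchanged.
    """
    p = np.asarray(p_list, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    if method == "benjamini_hochberg":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"method must be one of {CORRECTIONS}")


@dataclass(frozen=True)
class ComparisonResult:
    condition_a: str
    condition_b: str
    parameter: str
    n_a: int
    n_b: int
    u_statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    significant: bool
    testable: bool = True


def pairwise_comparison_table(
    exp: Experiment,
    parameter: str = "speed",
    conditions: Sequence[str] | None = None,
    alpha: float = 0.05,
    method: str = "benjamini_hochberg",
    level: str = "trajectory_centric",
    track_ids: set | None = None,
    mode: str = "auto",
) -> list[ComparisonResult]:
    """Mann-Whitney U on every unordered pair of conditions.

    ``parameter`` is ``speed`` or ``ep_dr``; values are pooled per
    condition across replicate wells at the chosen level. ``track_ids``
    (from a quality-control report) restricts testing to retained tracks;
    omit it to analyse the raw data. Correction is applied over the full
    pair set; pairs with an empty side are flagged untestable and excluded
    from the correction family.
    """
    if parameter not in ("speed", "ep_dr"):
        raise ValueError("parameter must be 'speed' or 'ep_dr'")
    if method not in CORRECTIONS:
        raise ValueError(f"method must be one of {CORRECTIONS}")
    names = list(conditions) if conditions else exp.condition_names
    if len(names) < 2:
        raise ValueError("need at least two conditions to compare")

    samples = {
        name: collect_distribution(
            exp, parameter, level=level, scope="condition",
            selection=name, track_ids=track_ids,
        ).values
        for name in names
    }
    pairs = list(itertools.combinations(names, 2))
    raw, stats, testable = [], [], []
    for a, b in pairs:
        va, vb = samples[a], samples[b]
        if len(va) == 0 or len(vb) == 0:
            testable.append(False)
            stats.append(math.nan)
            raw.append(math.nan)
        else:
            u, p = mann_whitney_u(va, vb, mode=mode)
            testable.append(True)
            stats.append(u)
            raw.append(p)

    ok = np.array(testable)
    adjusted = np.full(len(pairs), math.nan)
    if ok.any():
        adjusted[ok] = adjust_pvalues(np.array(raw)[ok], method)

    results = []
    for i, (a, b) in enumerate(pairs):
        results.append(ComparisonResult(
            condition_a=a, condition_b=b, parameter=parameter,
            n_a=len(samples[a]), n_b=len(samples[b]),
            u_statistic=stats[i], p_raw=raw[i], p_adjusted=adjusted[i],
            method=method,
            significant=bool(ok[i] and adjusted[i] < alpha),
            testable=bool(ok[i]),
        ))
    return results


def comparison_matrix(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Square conditions × conditions matrix of adjusted p-values."""
    names = []
    for r in results:
        for n in (r.condition_a, r.condition_b):
            if n not in names:
                names.append(n)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for r in results:
        mat.loc[r.condition_a, r.condition_b] = r.p_adjusted
        mat.loc[r.condition_b, r.condition_a] = r.p_adjusted
    return mat


# ---------------------------------------------------------------------------
# Plate-level scoring
# ---------------------------------------------------------------------------

_MAD_SCALE = 1.4826


def robust_zscore(per_well_values: Sequence[float]) -> np.ndarray:
    """Robust z*-score of each well against the plate median and MAD."""
    x = np.asarray(per_well_values, dtype=float)
    if len(x) < 3:
        raise ValueError("robust z*-score needs at least 3 wells")
    mad = sps.median_abs_deviation(x)
    if mad == 0:
        raise ValueError(
            "plate MAD is 0 (more than half the wells identical); "
            "robust z*-score undefined — use a mean/median metric instead"
        )
    return (x - np.median(x)) / (_MAD_SCALE * mad)


def plate_scores(
    exp: Experiment,
    metric: str = "median_speed",
    robust_z_base: str = "median_speed",
) -> pd.DataFrame:
    """Per-well summary metric for plate heatmaps.

    Metrics: track count, mean/median trajectory-centric speed,
    mean/median directionality (ep_dr), or the robust z*-score of
    ``robust_z_base`` across the plate's data-bearing wells.
    """
    if metric not in PLATE_METRICS:
        raise ValueError(f"metric must be one of {PLATE_METRICS}")
    rows = []
    for cond, well in exp.wells():
        speeds, eps = [], []
        for t in well.trajectories:
            s = summarize_track(t, exp.frame_interval_min)
            if not s.degenerate:
                speeds.append(s.track_speed)
                eps.append(s.ep_dr)
        rec = {"condition": cond.name, "well": well.label,
               "row": well.row, "column": well.column,
               "n_tracks": well.n_tracks}
        rec["mean_speed"] = float(np.mean(speeds)) if speeds else math.nan
        rec["median_speed"] = float(np.median(speeds)) if speeds else math.nan
        rec["mean_directionality"] = float(np.mean(eps)) if eps else math.nan
        rec["median_directionality"] = float(np.median(eps)) if eps else math.nan
        rows.append(rec)
    table = pd.DataFrame(rows)
    if metric == "robust_z":
        base = table[robust_z_base].to_numpy()
        mask = np.isfinite(base)
        z = np.full(len(base), math.nan)
        z[mask] = robust_zscore(base[mask])
        table["robust_z"] = z
    table["value"] = table[metric]
    return table
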