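"""Masked Pearson colocalization with Costes automatic thresholding.

The Costes procedure removes the arbitrariness of choosing a background
threshold for colocalization: channel B is regressed on channel A by
ordinary least squares (B ~ a*A + b), then a candidate threshold T_A is
lowered through the observed intensity range with T_B = a*T_A + b tied to
it, and the scan stops at the first T_A for which the Pearson correlation
of the sub-threshold voxels drops to (or below) zero. Voxels above both
thresholds are the signal; their correlation r_above is reported alongside
the whole-mask r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ColocResult", "GroupComparison", "pearson_r", "costes_threshold", "welch_t_test"]


@dataclass
class ColocResult:
    r_all: float
    slope: float
    intercept: float
    threshold_a: float
    threshold_b: float
    r_below: float
    r_above: float
    n_above: int
    flag: str = ""


@dataclass
class GroupComparison:
    n1: int
    n2: int
    mean1: float
    mean2: float
    sem1: float
    sem2: float
    t: float
    df: float
    p: float


def _as_masked(a, b, mask):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have identical shapes")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the channels")
    if not mask.any():
        raise ValueError("mask is empty")
    return a[mask], b[mask]


def pearson_r(a, b, mask=None) -> float:
    """Pearson correlation over the masked voxels.

    Raises on fewer than two voxels or zero variance in either channel
    (rather than returning NaN).
    """
    av, bv = _as_masked(a, b, mask)
    return _r(av, bv)


def _r(av: np.ndarray, bv: np.ndarray) -> float:
    if av.size < 2:
        raise ValueError("need at least 2 masked voxels")
    ac = av - av.mean()
    bc = bv - bv.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        raise ValueError("zero variance in a channel; Pearson r undefined")
    return float((ac * bc).sum() / denom)


def _r_or_nan(av, bv) -> float:
    try:
        return _r(av, bv)
    except ValueError:
        return np.nan


def costes_threshold(
    a,
    b,
    mask=None,
    max_levels: int = 4096,
    below: str = "and",
) -> ColocResult:
    """Automatic paired thresholds by the descending-scan Costes procedure.

    Candidate T_A values are the sorted distinct masked intensities of A
    (or ``max_levels`` evenly spaced levels when there are more distinct
    values than that), scanned downward; T_B = slope*T_A + intercept. The
    scan stops at the first T_A whose sub-threshold voxel set (A <= T_A and
    B <= T_B with ``below='and'``, or-combination with ``'or'``) has
    Pearson r <= 0; if no candidate reaches zero the candidate minimizing
    r_below is returned. Levels whose sub-threshold set is too small or
    degenerate for a correlation are skipped.
    """
    av, bv = _as_masked(a, b, mask)
    r_all = _r(av, bv)
    slope, intercept = np.polyfit(av, bv, 1)
    result = ColocResult(
        r_all=r_all,
        slope=float(slope),
        intercept=float(intercept),
        threshold_a=np.nan,
        threshold_b=np.nan,
        r_below=np.nan,
        r_above=np.nan,
        n_above=0,
    )
    if slope <= 0:
        result.flag = "no positive-correlation threshold (slope <= 0)"
        return result

    levels = np.unique(av)
    if levels.size > max_levels:
        levels = np.linspace(levels[0], levels[-1], max_levels)
    if below not in ("and", "or"):
        raise ValueError("below must be 'and' or 'or'")

    best = None  # (r_below, t_a)
    stop = None
    for t_a in levels[::-1]:
        t_b = slope * t_a + intercept
        if below == "and":
            sel = (av <= t_a) & (bv <= t_b)
        else:
            sel = (av <= t_a) | (bv <= t_b)
        r_below = _r_or_nan(av[sel], bv[sel])
        if np.isnan(r_below):
            continue
        if best is None or r_below <= best[0]:
            best = (r_below, t_a)  # ties go to the lower threshold
        if r_below <= 0:
            stop = (r_below, t_a)
            break
    if stop is None:
        if best is None:
            result.flag = "scan degenerate: no computable sub-threshold correlation"
            return result
        stop = best
        result.flag = "scan exhausted: r_below never reached zero"

    r_below, t_a = stop
    t_b = slope * t_a + intercept
    above = (av > t_a) & (bv > t_b)
    result.threshold_a = float(t_a)
    result.threshold_b = float(t_b)
    result.r_below = float(r_below)
    result.n_above = int(above.sum())
    r_above = _r_or_nan(av[above], bv[above])
    if np.isnan(r_above) and not result.flag:
        result.flag = "r_above undefined: fewer than 2 supra-threshold voxels"
    result.r_above = float(r_above)
    return result


def welch_t_test(sample1, sample2) -> GroupComparison:
    """Two-sided unpaired t-test with Welch's correction.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), degrees of freedom by
    Welch-Satterthwaite, p from Student's t. Two identical constant samples
    give t = 0, p = 1 by convention.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1 = x1.var(ddof=1)
    v2 = x2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        t_stat, p, df = (0.0, 1.0, float(n1 + n2 - 2)) if x1.mean() == x2.mean() else (
            np.inf if x1.mean() > x2.mean() else -np.inf,
            0.0,
            float(n1 + n2 - 2),
        )
    else:
        res = stats.ttest_ind(x1, x2, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        se1, se2 = v1 / n1, v2 / n2
        df = (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
    return GroupComparison(
        n1=n1,
        n2=n2,
        mean1=float(x1.mean()),
        mean2=float(x2.mean()),
        sem1=float(np.sqrt(v1 / n1)),
        sem2=float(np.sqrt(v2 / n2)),
        t=t_stat,
        df=float(df),
        p=p,
    )
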