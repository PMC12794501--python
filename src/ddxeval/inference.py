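"""Statistical machinery: proportion CIs, variance/mean comparisons,
Games–Howell post hoc tests, and univariable logistic regression.

The group comparison of precision scores proceeds as in a classical
heteroscedastic one-way layout: Levene's test checks homogeneity of
variances, a one-way ANOVA tests equality of means, and — because group
sizes and variances differ — pairwise contrasts use the Games–Howell
procedure (Welch standard errors, Welch–Satterthwaite degrees of
freedom, and the studentized-range distribution for multiplicity
control).  Proportions are interval-estimated with the Wald normal
approximation, which is what reproduces the published interval bounds.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairwiseComparison",
    "OddsRatioResult",
    "SeparationError",
    "wald_ci",
    "levene_test",
    "oneway_anova",
    "games_howell",
    "logistic_or",
]


def wald_ci(successes: float, trials: int, conf: float = 0.95) -> tuple[float, float]:
    """Wald (normal-approximation) CI for a binomial proportion.

    Returns ``(low, high)`` on the *percentage* scale:
    100·(p̂ ± z·sqrt(p̂(1−p̂)/n)).  The interval is symmetric about the
    point estimate and is deliberately not clipped to [0, 100]; with
    zero (or all) successes it degenerates to a point.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    if not 0.0 < conf < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    p = successes / trials
    z = stats.norm.ppf(0.5 + conf / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / trials)
    return 100.0 * (p - half), 100.0 * (p + half)


def _check_groups(samples: Sequence[Sequence[float]], min_size: int = 2) -> list[np.ndarray]:
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < min_size:
            raise ValueError(f"group {i} has fewer than {min_size} observations")
    return groups


def levene_test(samples: Sequence[Sequence[float]], center: str = "mean") -> tuple[float, float]:
    """Levene's test for homogeneity of variances.

    ``center="mean"`` is the classical Levene statistic (absolute
    deviations from group means); ``center="median"`` gives the
    Brown–Forsythe variant.  Returns ``(statistic, p)``.  Degenerate
    input with no spread anywhere yields ``(0.0, 1.0)``.
    """
    groups = _check_groups(samples)
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    centers = [np.mean(g) if center == "mean" else np.median(g) for g in groups]
    if all(np.all(g == c) for g, c in zip(groups, centers)):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.levene(*groups, center=center)
    if np.isnan(stat):  # all deviation means equal with zero spread
        return 0.0, 1.0
    return float(stat), float(p)


def oneway_anova(samples: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns ``(F, p)``.

    All-constant input (zero between- and within-group variability)
    returns ``F = 0, p = 1`` rather than NaN.
    """
    groups = _check_groups(samples)
    pooled = np.concatenate(groups)
    if pooled.size <= len(groups):
        raise ValueError("total observations must exceed the number of groups")
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass(frozen=True)
class PairwiseComparison:
    """One Games–Howell contrast: mean difference, CI, and p value.

    ``flagged`` marks numerically fragile contrasts (a zero-variance
    group), where the Welch machinery degenerates.
    """

    group_a: str
    group_b: str
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    se: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_diff <= self.ci_high):
            raise ValueError("confidence interval must bracket the mean difference")


def games_howell(
    samples: Mapping[str, Sequence[float]], conf: float = 0.95
) -> list[PairwiseComparison]:
    """Games–Howell pairwise comparisons for unequal variances/sizes.

    For each pair (a, b): the Welch standard error
    ``se = sqrt(v_a/n_a + v_b/n_b)``, Welch–Satterthwaite degrees of
    freedom, p value from the studentized-range distribution with k
    groups (the statistic is ``|diff|/se · sqrt(2)``), and a CI of
    ``diff ± q_crit/sqrt(2) · se``.
    """
    names = list(samples)
    groups = dict(zip(names, _check_groups([samples[n] for n in names])))
    k = len(names)
    out: list[PairwiseComparison] = []
    for a, b in itertools.combinations(names, 2):
        ga, gb = groups[a], groups[b]
        na, nb = ga.size, gb.size
        va, vb = ga.var(ddof=1), gb.var(ddof=1)
        diff = float(ga.mean() - gb.mean())
        flagged = va == 0.0 or vb == 0.0
        se2 = va / na + vb / nb
        if se2 == 0.0:
            # identical constants: no evidence of any difference
            out.append(
                PairwiseComparison(a, b, diff, diff, diff, 1.0 if diff == 0 else 0.0,
                                   df=float(na + nb - 2), se=0.0, flagged=True)
            )
            continue
        se = float(np.sqrt(se2))
        denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        df = float(se2**2 / denom) if denom > 0 else float(na + nb - 2)
        q_stat = abs(diff) / se * np.sqrt(2.0)
        p = float(stats.studentized_range.sf(q_stat, k, df))
        q_crit = float(stats.studentized_range.ppf(conf, k, df))
        half = q_crit / np.sqrt(2.0) * se
        out.append(
            PairwiseComparison(
                a, b, diff, diff - half, diff + half, p, df=df, se=se, flagged=flagged
            )
        )
    return out


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with Wald interval and p value from a univariable
    logistic model."""

    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the odds ratio")


class SeparationError(ValueError):
    """The logistic model is (quasi-)separated; the MLE does not exist."""


def logistic_or(
    outcome: Sequence[int], predictor: Sequence[float], conf: float = 0.95
) -> OddsRatioResult:
    """Univariable logistic regression odds ratio per predictor unit.

    Fits ``logit P(y=1) = b0 + b1·x`` by maximum likelihood and returns
    ``exp(b1)`` with a Wald CI and p value.  Complete or quasi-complete
    separation raises :class:`SeparationError` instead of reporting an
    astronomically large estimate.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("outcome and predictor must be equal-length 1-D vectors")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("outcome must be binary 0/1")
    if classes.size < 2:
        raise ValueError("outcome must contain both classes")

    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from None
    except np.linalg.LinAlgError as exc:
        raise SeparationError(f"singular information matrix: {exc}") from None
    slope, se = fit.params[1], fit.bse[1]
    if not np.isfinite(se) or abs(slope) > 20:
        raise SeparationError("slope diverged; data are separated")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    return OddsRatioResult(
        or_estimate=float(np.exp(slope)),
        ci_low=float(np.exp(slope - z * se)),
        ci_high=float(np.exp(slope + z * se)),
        p_value=float(fit.pvalues[1]),
    )
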