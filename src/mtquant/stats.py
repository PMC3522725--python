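"""Group statistics: one-way ANOVA, Dunnett many-to-one comparisons,
Student-Newman-Keuls all-pairwise comparisons, two-sample t-tests,
viability normalization and dose-response summarization.

Dunnett critical values and p-values are computed by deterministic
Gauss-Hermite / Gauss-Legendre quadrature of the equicorrelated
multivariate-t probability — no hard-coded tables — so arbitrary group
counts and (unbalanced) sample sizes are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import DegenerateVarianceError, ParameterError

__all__ = [
    "GroupData",
    "Comparison",
    "TestResult",
    "ViabilityResult",
    "DoseResponseSummary",
    "one_way_anova",
    "dunnett",
    "dunnett_critical_value",
    "dunnett_prob",
    "snk",
    "two_sample_t",
    "viability_percent",
    "dose_response_summary",
    "classify_shape",
]


@dataclass
class GroupData:
    """Label and raw measurement values for one experimental group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        return float(self.values.std(ddof=1) / np.sqrt(self.n))


@dataclass(frozen=True)
class Comparison:
    """One labelled comparison inside a multiple-comparison result."""

    label: str
    estimate: float
    statistic: float
    p_value: float
    significant: bool


@dataclass
class TestResult:
    """Outcome of a statistical test, with per-comparison detail when the
    test is a multiple-comparison procedure."""

    method: str
    statistic: float
    p_value: float
    alpha: float
    comparisons: list[Comparison] = field(default_factory=list)
    df: tuple[float, float] | float | None = None

    @property
    def significant_labels(self) -> list[str]:
        return [c.label for c in self.comparisons if c.significant]


@dataclass
class ViabilityResult:
    """Per-group viability as percent of the control-group mean."""

    control_label: str
    percent_of_control: dict[str, float]
    sem: dict[str, float]
    normalized_groups: list[GroupData]


@dataclass
class DoseResponseSummary:
    """Per-concentration summary of a plate with Dunnett flags vs vehicle
    and a run-based shape label."""

    concentrations: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    flagged: np.ndarray
    shape: str
    test: TestResult


def _validate_groups(groups: list[GroupData], min_groups: int = 2) -> None:
    if len(groups) < min_groups:
        raise ParameterError(f"need at least {min_groups} groups")
    for g in groups:
        if g.n < 2:
            raise ParameterError(f"group {g.label!r} has n={g.n} < 2")


def _pooled_within(groups: list[GroupData]) -> tuple[float, int]:
    """Pooled within-group mean square and its degrees of freedom."""
    n_total = sum(g.n for g in groups)
    df = n_total - len(groups)
    ssw = sum(((g.values - g.mean) ** 2).sum() for g in groups)
    if ssw == 0:
        raise DegenerateVarianceError("zero within-group variance in every group")
    return ssw / df, df


def one_way_anova(groups: list[GroupData], alpha: float = 0.05) -> TestResult:
    """Classical equal-variance one-way ANOVA F test."""
    _validate_groups(groups)
    msw, df_w = _pooled_within(groups)
    grand = np.concatenate([g.values for g in groups]).mean()
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    df_b = len(groups) - 1
    f_stat = (ssb / df_b) / msw
    p = float(stats.f.sf(f_stat, df_b, df_w))
    return TestResult(
        method="one_way_anova",
        statistic=float(f_stat),
        p_value=p,
        alpha=alpha,
        df=(df_b, df_w),
    )


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

_GH_NODES = 96
_GL_NODES = 64


@lru_cache(maxsize=64)
def _quadrature(df: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gauss-Hermite nodes for the shared normal factor and chi-distribution
    nodes (via inverse-CDF Gauss-Legendre) for the scale factor."""
    z, wz = special.roots_hermitenorm(_GH_NODES)
    wz = wz / np.sqrt(2 * np.pi)
    t, wu = special.roots_legendre(_GL_NODES)
    t = 0.5 * (t + 1.0)
    wu = 0.5 * wu
    u = stats.chi.ppf(t, df) / np.sqrt(df)
    return z, wz, u, wu


def dunnett_prob(q: float, lam: np.ndarray, df: int) -> float:
    """P(max_i |T_i| <= q) for the many-to-one comparison t statistics.

    ``T_i = (lam_i Z0 + sqrt(1 - lam_i^2) Z_i) / U`` with shared standard
    normal ``Z0``, independent ``Z_i`` and ``U = sqrt(chi2_df / df)``;
    ``lam_i = sqrt(n_i / (n_i + n_0))`` gives corr(T_i, T_j) = lam_i lam_j.
    """
    lam = np.asarray(lam, dtype=float)
    gam = np.sqrt(1.0 - lam**2)
    z, wz, u, wu = _quadrature(int(df))
    # shape (nu, nz, k)
    upper = (q * u[:, None, None] - lam * z[None, :, None]) / gam
    lower = (-q * u[:, None, None] - lam * z[None, :, None]) / gam
    probs = np.prod(stats.norm.cdf(upper) - stats.norm.cdf(lower), axis=2)
    return float(wu @ probs @ wz)


def dunnett_critical_value(
    n_treatments: np.ndarray | list[int] | int,
    n_control: int,
    df: int,
    alpha: float = 0.05,
) -> float:
    """Two-sided family-wise critical value for Dunnett's procedure."""
    if np.isscalar(n_treatments):
        raise ParameterError("n_treatments must be a sequence of group sizes")
    n_t = np.asarray(n_treatments, dtype=float)
    lam = np.sqrt(n_t / (n_t + n_control))
    return float(
        optimize.brentq(lambda q: dunnett_prob(q, lam, df) - (1 - alpha), 0.5, 12.0)
    )


def dunnett(
    groups: list[GroupData], control_label: str, alpha: float = 0.05
) -> TestResult:
    """Dunnett's many-to-one post-test: each treatment vs the control.

    P-values are family-wise: ``p_i = P(max_j |T_j| >= |t_i|)`` under the
    equicorrelated multivariate-t null, so a comparison is flagged exactly
    when ``|t_i|`` exceeds the family-wise critical value.
    """
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise ParameterError(f"control group {control_label!r} not present")
    control = groups[labels.index(control_label)]
    treatments = [g for g in groups if g.label != control_label]
    if not treatments:
        raise ParameterError("need at least one treatment group")
    _validate_groups(groups)
    msw, df_w = _pooled_within(groups)

    n_t = np.array([g.n for g in treatments], dtype=float)
    lam = np.sqrt(n_t / (n_t + control.n))
    crit = float(
        optimize.brentq(lambda q: dunnett_prob(q, lam, df_w) - (1 - alpha), 0.5, 12.0)
    )

    comparisons = []
    for g in treatments:
        se = np.sqrt(msw * (1.0 / g.n + 1.0 / control.n))
        t_stat = (g.mean - control.mean) / se
        p = 1.0 - dunnett_prob(abs(t_stat), lam, df_w)
        p = min(max(p, 0.0), 1.0)
        comparisons.append(
            Comparison(
                label=g.label,
                estimate=g.mean - control.mean,
                statistic=float(t_stat),
                p_value=p,
                significant=bool(abs(t_stat) > crit),
            )
        )
    max_t = max(abs(c.statistic) for c in comparisons)
    return TestResult(
        method="dunnett",
        statistic=float(max_t),
        p_value=min(c.p_value for c in comparisons),
        alpha=alpha,
        comparisons=comparisons,
        df=df_w,
    )


# ---------------------------------------------------------------------------
# Student-Newman-Keuls all-pairwise comparisons
# ---------------------------------------------------------------------------


def snk(groups: list[GroupData], alpha: float = 0.05) -> TestResult:
    """Student-Newman-Keuls stepwise studentized-range procedure.

    Means are ordered; the extremes of each span are tested against the
    studentized-range critical value for that span, and any span found
    non-significant absorbs (protects) all comparisons nested inside it.
    """
    _validate_groups(groups)
    msw, df_w = _pooled_within(groups)
    ordered = sorted(groups, key=lambda g: g.mean)
    k = len(ordered)

    decisions: dict[tuple[int, int], Comparison] = {}

    def se_pair(gi: GroupData, gj: GroupData) -> float:
        # Tukey-Kramer style standard error for unequal n
        return float(np.sqrt(msw / 2.0 * (1.0 / gi.n + 1.0 / gj.n)))

    def mark_ns(i: int, j: int) -> None:
        for a in range(i, j + 1):
            for b in range(a + 1, j + 1):
                if (a, b) not in decisions:
                    gi, gj = ordered[a], ordered[b]
                    q = (gj.mean - gi.mean) / se_pair(gi, gj)
                    span = b - a + 1
                    p = float(stats.studentized_range.sf(q, span, df_w))
                    decisions[(a, b)] = Comparison(
                        label=f"{gi.label} vs {gj.label}",
                        estimate=gj.mean - gi.mean,
                        statistic=q,
                        p_value=min(max(p, 0.0), 1.0),
                        significant=False,
                    )

    def test_span(i: int, j: int) -> None:
        if (i, j) in decisions:
            return
        gi, gj = ordered[i], ordered[j]
        span = j - i + 1
        q = (gj.mean - gi.mean) / se_pair(gi, gj)
        p = float(stats.studentized_range.sf(q, span, df_w))
        p = min(max(p, 0.0), 1.0)
        if p < alpha:
            decisions[(i, j)] = Comparison(
                label=f"{gi.label} vs {gj.label}",
                estimate=gj.mean - gi.mean,
                statistic=q,
                p_value=p,
                significant=True,
            )
            if span > 2:
                test_span(i, j - 1)
                test_span(i + 1, j)
        else:
            mark_ns(i, j)

    test_span(0, k - 1)
    # spans not reached because an enclosing span was significant but the
    # recursion narrowed elsewhere: test remaining pairs top-down by span
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            test_span(i, i + span - 1)

    comparisons = [decisions[key] for key in sorted(decisions)]
    max_q = max(c.statistic for c in comparisons)
    return TestResult(
        method="snk",
        statistic=float(max_q),
        p_value=min(c.p_value for c in comparisons),
        alpha=alpha,
        comparisons=comparisons,
        df=df_w,
    )


def two_sample_t(a: GroupData, b: GroupData, alpha: float = 0.05, welch: bool = False) -> TestResult:
    """Two-sample t-test (pooled by default; Welch behind a flag)."""
    _validate_groups([a, b])
    t_stat, p = stats.ttest_ind(a.values, b.values, equal_var=not welch)
    return TestResult(
        method="welch_t" if welch else "student_t",
        statistic=float(t_stat),
        p_value=float(p),
        alpha=alpha,
    )


def viability_percent(groups: list[GroupData], control_label: str) -> ViabilityResult:
    """Scale every absorbance so the control-group mean is exactly 100%."""
    labels = [g.label for g in groups]
    if control_label not in labels:
        raise ParameterError(f"control group {control_label!r} not present")
    control = groups[labels.index(control_label)]
    if control.n == 0:
        raise ParameterError("control group is empty")
    ref = control.mean
    if ref <= 0:
        raise ParameterError("control group mean must be positive")
    scale = 100.0 / ref
    normalized = [GroupData(g.label, g.values * scale) for g in groups]
    return ViabilityResult(
        control_label=control_label,
        percent_of_control={g.label: g.mean for g in normalized},
        sem={g.label: g.sem for g in normalized},
        normalized_groups=normalized,
    )


def classify_shape(flagged: np.ndarray) -> str:
    """Run-based shape label for a sorted concentration series.

    ``bimodal``: >= 2 runs of flagged concentrations separated by at least
    one unflagged one; ``monotone``: a single run ending at the top
    concentration; ``flat``: nothing flagged; ``peaked``: a single interior
    run (documented fallback).
    """
    flagged = np.asarray(flagged, dtype=bool)
    runs = 0
    prev = False
    for f in flagged:
        if f and not prev:
            runs += 1
        prev = f
    if runs == 0:
        return "flat"
    if runs >= 2:
        return "bimodal"
    return "monotone" if flagged[-1] else "peaked"


def dose_response_summary(
    plate: pd.DataFrame,
    measurement: str = "normalized_fau",
    control_label: str = "vehicle",
    alpha: float = 0.05,
) -> DoseResponseSummary:
    """Per-concentration mean +/- SEM with Dunnett flags vs vehicle and a
    shape label.

    ``plate`` must contain ``condition``, ``concentration_M`` and the
    ``measurement`` column (run :func:`~mtquant.intensity.icw_normalize`
    first for plate-reader tables).
    """
    if control_label not in set(plate["condition"]):
        raise ParameterError(f"vehicle group {control_label!r} missing from plate")
    vehicle = plate.loc[plate["condition"] == control_label, measurement].to_numpy()
    treated = plate.loc[plate["condition"] != control_label]
    concs = np.sort(treated["concentration_M"].unique())
    if len(concs) < 3:
        raise ParameterError("need at least 3 concentrations")

    groups = [GroupData(control_label, vehicle)]
    for c in concs:
        vals = treated.loc[treated["concentration_M"] == c, measurement].to_numpy()
        groups.append(GroupData(f"{c:.3e}", vals))
    result = dunnett(groups, control_label, alpha=alpha)

    means = np.array([g.mean for g in groups[1:]])
    sems = np.array([g.sem for g in groups[1:]])
    flagged = np.array([c.significant for c in result.comparisons])
    return DoseResponseSummary(
        concentrations=concs,
        means=means,
        sems=sems,
        flagged=flagged,
        shape=classify_shape(flagged),
        test=result,
    )
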