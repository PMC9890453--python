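"""NHST, two-one-sided equivalence tests (TOST), and the joint-outcome
scenario classifier.

A contrast is judged twice: against the point null (conventional NHST) and
against a region of practical equivalence to zero, [-0.5, +0.5] uV by
default.  The TOST rejects when *both* one-sided tests against the region
bounds reject; its reported statistic is the side with the smaller |t| (the
larger one-sided p).  Combining the two tests yields six canonical outcome
scenarios — plus a seventh for the both-significant corner case — each with
a reporting directive:

* S1 / S2 — NHST significant, TOST not (split by the sign of the estimate):
  the effect differs from zero; report NHST only (95% CI).
* S3 — TOST significant, NHST not: the effect is equivalent to the null;
  report the ET only, smaller-|t| side (90% CI).
* S4 / S5 / S6 — neither significant, inconclusive; split by where the 90%
  CI sits relative to the region (spanning both bounds / overlapping the
  lower bound / overlapping the upper bound); report both tests.
* S_both — both significant (a nonzero yet practically-equivalent effect);
  report both, flagged.

Bonferroni corrections multiply the reported p by the family size, capped
at 1; significance decisions use the corrected p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EquivalenceRegion:
    """Region of practical equivalence to zero on the contrast scale (uV)."""

    lower: float = -0.5
    upper: float = 0.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")
        if not self.lower <= 0.0 <= self.upper:
            raise ValueError("the region must contain zero")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class NHSTResult:
    t: float
    df: float
    p: float               # two-sided, Bonferroni-corrected if family > 1
    p_uncorrected: float
    ci95: tuple
    family: int = 1
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass
class TOSTResult:
    t_lower: float         # (b - lower)/SE, tested right-tail
    t_upper: float         # (b - upper)/SE, tested left-tail
    reported_t: float      # side with the smaller |t|
    df: float
    p: float               # max one-sided p, Bonferroni-corrected
    p_uncorrected: float
    ci90: tuple
    family: int = 1
    alpha: float = 0.05

    @property
    def equivalent(self) -> bool:
        return self.p < self.alpha


def nhst(
    b: float, se: float, df: float, alpha: float = 0.05, family: int = 1
) -> NHSTResult:
    """Two-sided t test of the contrast against zero, with a 95% CI."""
    if se <= 0:
        raise ValueError("SE must be positive")
    if df <= 0:
        raise ValueError("df must be positive")
    t = b / se
    p_unc = 2.0 * stats.t.sf(abs(t), df)
    # Bonferroni-adjusted CI, matching the adjusted p (emmeans convention)
    tcrit = stats.t.ppf(1.0 - 0.025 / family, df)
    return NHSTResult(
        t=t,
        df=df,
        p=min(1.0, family * p_unc),
        p_uncorrected=p_unc,
        ci95=(b - tcrit * se, b + tcrit * se),
        family=family,
        alpha=alpha,
    )


def tost(
    b: float,
    se: float,
    df: float,
    region: EquivalenceRegion = EquivalenceRegion(),
    family: int = 1,
) -> TOSTResult:
    """Two one-sided tests against the equivalence region bounds.

    Equivalence is declared when the larger of the two one-sided p values
    (after Bonferroni correction by the family size) falls below alpha;
    this is equivalent to both one-sided tests rejecting.  A 90% CI is
    attached, per the equivalence-CI convention.
    """
    if se <= 0:
        raise ValueError("SE must be positive")
    t_lower = (b - region.lower) / se
    t_upper = (b - region.upper) / se
    p_lower = stats.t.sf(t_lower, df)   # H0: b <= lower, reject for large t
    p_upper = stats.t.cdf(t_upper, df)  # H0: b >= upper, reject for small t
    p_unc = max(p_lower, p_upper)
    reported_t = t_lower if abs(t_lower) < abs(t_upper) else t_upper
    # Bonferroni-adjusted 90% CI: corrected p < alpha <=> CI inside region
    tcrit = stats.t.ppf(1.0 - 0.05 / family, df)
    return TOSTResult(
        t_lower=t_lower,
        t_upper=t_upper,
        reported_t=reported_t,
        df=df,
        p=min(1.0, family * p_unc),
        p_uncorrected=p_unc,
        ci90=(b - tcrit * se, b + tcrit * se),
        family=family,
        alpha=region.alpha,
    )


@dataclass(frozen=True)
class ScenarioLabel:
    id: str
    description: str
    directive: str  # "report NHST only" | "report ET only" | "report both"


_SCENARIOS = {
    "S1": ScenarioLabel(
        "S1", "NHST significant, ET not; positive effect", "report NHST only"
    ),
    "S2": ScenarioLabel(
        "S2", "NHST significant, ET not; negative effect", "report NHST only"
    ),
    "S3": ScenarioLabel(
        "S3", "ET significant, NHST not: equivalent to null", "report ET only"
    ),
    "S4": ScenarioLabel(
        "S4", "inconclusive; CI spans both region bounds", "report both"
    ),
    "S5": ScenarioLabel(
        "S5", "inconclusive; CI overlaps the lower bound", "report both"
    ),
    "S6": ScenarioLabel(
        "S6", "inconclusive; CI overlaps the upper bound", "report both"
    ),
    "S_both": ScenarioLabel(
        "S_both",
        "NHST and ET both significant: nonzero but practically equivalent",
        "report both",
    ),
}


def classify_scenario(
    nhst_result: NHSTResult,
    tost_result: TOSTResult,
    region: EquivalenceRegion = EquivalenceRegion(),
) -> ScenarioLabel:
    """Assign the joint NHST/ET outcome to one of the seven scenarios.

    The classifier is total: every input yields exactly one label.  The
    inconclusive scenarios are split by the position of the 90% CI relative
    to the region bounds; in the corner case where neither test is
    significant yet the CI lies inside the region (possible once a
    Bonferroni correction is applied), the label follows the reported
    (smaller-|t|) side of the TOST.
    """
    if abs(nhst_result.alpha - tost_result.alpha) > 1e-12:
        raise ValueError("NHST and TOST were run at different alpha levels")
    sig_n = nhst_result.significant
    sig_e = tost_result.equivalent
    if sig_n and not sig_e:
        b = nhst_result.t  # sign of t == sign of b
        return _SCENARIOS["S1" if b > 0 else "S2"]
    if sig_e and not sig_n:
        return _SCENARIOS["S3"]
    if sig_n and sig_e:
        return _SCENARIOS["S_both"]
    lo, hi = tost_result.ci90
    below = lo < region.lower
    above = hi > region.upper
    if below and above:
        return _SCENARIOS["S4"]
    if below:
        return _SCENARIOS["S5"]
    if above:
        return _SCENARIOS["S6"]
    # CI inside the region but corrected TOST not significant
    return _SCENARIOS["S5" if tost_result.reported_t == tost_result.t_lower else "S6"]


@dataclass
class ContrastResult:
    """A linear-contrast estimate with its NHST/ET verdicts."""

    label: str
    b: float
    se: float
    df: float
    t: float
    p_nhst: float
    p_tost: float
    ci95: tuple
    ci90: tuple
    family: int
    scenario: ScenarioLabel
    nhst: NHSTResult = field(repr=False, default=None)
    tost: TOSTResult = field(repr=False, default=None)
    df_method: str = "residual"

    @classmethod
    def from_estimate(
        cls,
        label: str,
        b: float,
        se: float,
        df: float,
        region: EquivalenceRegion = EquivalenceRegion(),
        family: int = 1,
        df_method: str = "residual",
    ) -> "ContrastResult":
        n = nhst(b, se, df, alpha=region.alpha, family=family)
        e = tost(b, se, df, region=region, family=family)
        return cls(
            label=label,
            b=b,
            se=se,
            df=df,
            t=n.t,
            p_nhst=n.p,
            p_tost=e.p,
            ci95=n.ci95,
            ci90=e.ci90,
            family=family,
            scenario=classify_scenario(n, e, region),
            nhst=n,
            tost=e,
            df_method=df_method,
        )

    def to_row(self) -> dict:
        return {
            "contrast": self.label,
            "b": self.b,
            "SE": self.se,
            "df": self.df,
            "t": self.t,
            "p_nhst": self.p_nhst,
            "t_et": self.tost.reported_t if self.tost else np.nan,
            "p_tost": self.p_tost,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "ci90_low": self.ci90[0],
            "ci90_high": self.ci90[1],
            "family": self.family,
            "scenario": self.scenario.id,
            "directive": self.scenario.directive,
            "df_method": self.df_method,
        }
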