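"""RMST-difference non-inferiority testing against a clinical margin.

The comparison is on the restricted-mean-survival-time scale: the *loss*
of a test arm vs the reference is the difference in event-free months over
[0, tau], positive when the test arm is worse. Non-inferiority at margin
Delta (months) is declared when the upper bound of the two-sided 90% CI of
the loss stays below Delta — equivalently a one-sided z-test at alpha =
0.05 of H0: loss >= Delta, the standard pairing for non-inferiority
designs. A helper converts a published CI between confidence levels under
normal theory (the SE is recovered from the interval width), which is how
90% intervals are obtained from printed 95% ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .survstats import RMSTResult, kaplan_meier, rmst


@dataclass
class NIResult:
    """One non-inferiority comparison (test arm vs reference arm)."""

    comparison: tuple[str, str]
    loss: float
    se: float
    ci90: tuple[float, float]
    ci95: tuple[float, float]
    margin: float
    z: float
    p_noninf: float
    noninferior: bool

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["comparison"] = list(self.comparison)
        d["ci90"] = list(self.ci90)
        d["ci95"] = list(self.ci95)
        return d


def rmst_difference(a: RMSTResult, b: RMSTResult) -> tuple[float, float]:
    """Difference a - b of two independent-arm RMST estimates, with pooled SE."""
    if a.tau != b.tau:
        raise ValidationError(f"mismatched truncation times: {a.tau} vs {b.tau}")
    return a.estimate - b.estimate, float(np.sqrt(a.se**2 + b.se**2))


def convert_ci(
    point: float,
    ci_from: tuple[float, float],
    level_from: float,
    level_to: float,
) -> tuple[float, float]:
    """Re-express a normal-theory CI at another confidence level.

    The SE is recovered as (upper - lower) / (2 z_from) and the new
    interval is point +/- z_to * SE.
    """
    lower, upper = ci_from
    if upper < lower:
        raise ValidationError("CI upper bound below lower bound")
    if not (lower <= point <= upper):
        raise ValidationError("point estimate outside the given CI")
    if upper == lower:
        warnings.warn("degenerate (zero-width) interval; output is zero-width")
        return (point, point)
    z_from = stats.norm.ppf(0.5 + level_from / 2)
    z_to = stats.norm.ppf(0.5 + level_to / 2)
    se = (upper - lower) / (2 * z_from)
    return (point - z_to * se, point + z_to * se)


def ni_test(
    loss: float,
    se: float,
    margin: float,
    comparison: tuple[str, str] = ("test", "reference"),
) -> NIResult:
    """One-sided non-inferiority test of an RMST loss against a margin.

    z = (margin - loss) / se; p_noninf is the upper-tail normal
    probability under the boundary null (loss = margin). The decision is
    taken on the 90% CI: non-inferior iff its upper bound < margin, which
    coincides with z > 1.644854 (one-sided 0.05).
    """
    if se <= 0:
        raise ValidationError("se must be positive")
    if margin <= 0:
        raise ValidationError("margin must be positive")
    z90 = stats.norm.ppf(0.95)
    z95 = stats.norm.ppf(0.975)
    z = (margin - loss) / se
    # keep p strictly inside (0, 1) even when the normal tail saturates
    p = float(np.clip(stats.norm.sf(z), np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0)))
    ci90 = (loss - z90 * se, loss + z90 * se)
    ci95 = (loss - z95 * se, loss + z95 * se)
    return NIResult(
        comparison=comparison,
        loss=float(loss),
        se=float(se),
        ci90=ci90,
        ci95=ci95,
        margin=float(margin),
        z=float(z),
        p_noninf=p,
        noninferior=bool(ci90[1] < margin),
    )


def rmst_noninferiority(
    ipd: pd.DataFrame,
    reference_arm: str,
    tau: float,
    margin: float,
) -> list[NIResult]:
    """Full NI analysis of a pooled IPD table: each arm vs the reference.

    The loss of arm A is RMST(reference) - RMST(A) (positive = A worse),
    the sign convention under which the margin is a tolerated loss.
    """
    arms = sorted(ipd["arm"].unique())
    if reference_arm not in arms:
        raise ValidationError(f"reference arm {reference_arm!r} absent from IPD")
    ref_rmst = rmst(kaplan_meier(ipd, reference_arm), tau)
    results = []
    for arm in arms:
        if arm == reference_arm:
            continue
        arm_rmst = rmst(kaplan_meier(ipd, arm), tau)
        loss, se = rmst_difference(ref_rmst, arm_rmst)
        results.append(ni_test(loss, se, margin, comparison=(arm, reference_arm)))
    return results


def forest_data(results: Sequence[NIResult]) -> pd.DataFrame:
    """Forest-plot-ready table: one row per comparison, margin as a column."""
    if len(results) == 0:
        raise ValidationError("no results to tabulate")
    rows = []
    for r in results:
        rows.append(
            {
                "label": f"{r.comparison[0]} vs {r.comparison[1]}",
                "loss": r.loss,
                "ci90_lower": r.ci90[0],
                "ci90_upper": r.ci90[1],
                "margin": r.margin,
                "noninferior": r.noninferior,
            }
        )
    return pd.DataFrame(rows)
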