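"""Kaplan-Meier curve -> individual patient data reconstruction.

Given digitized survival clicks for one arm and the published
numbers-at-risk row, this module rebuilds a patient-level dataset whose KM
re-estimate reproduces the published curve (the classic curve-inversion
procedure used for secondary analyses of published trials).

The idea: within each risk-table interval the censoring pattern is assumed
uniform. For a candidate interval censoring count c, censoring times are
spread over the interval, the clicks are walked in time order, and an
integer event count is allocated at each click by inverting the
product-limit relation

    d_k = round(n_k * (1 - S_k / S_last_event)),

where n_k is the running at-risk count and S_last_event the reconstructed
KM value after the previous event allocation. Because the target is always
compared against the *reconstructed* curve, rounding residue at one click
carries to the next (largest-remainder behaviour over a vertical drop
digitized as several clicks). c is then adjusted by monotone integer
bisection until the implied at-risk count at the next boundary matches the
published one. The whole procedure is deterministic: no random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ReconstructionInfeasibleError, ValidationError
from .io_ingest import DigitizedCurve, RiskTable, make_ipd, validate_ipd
from .survstats import KMEstimate, kaplan_meier


@dataclass
class ReconstructionReport:
    """Fidelity and bookkeeping summary of one arm's reconstruction."""

    max_abs_dev: float
    rmse: float
    n_events_reconstructed: int
    n_censored_reconstructed: int
    risk_match: list[tuple[int, int]] = field(default_factory=list)
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "max_abs_dev": self.max_abs_dev,
            "rmse": self.rmse,
            "n_events_reconstructed": self.n_events_reconstructed,
            "n_censored_reconstructed": self.n_censored_reconstructed,
            "risk_match": [list(pair) for pair in self.risk_match],
            "converged": self.converged,
        }


def assign_intervals(curve: DigitizedCurve, risk: RiskTable) -> list[tuple[int, int]]:
    """Bin click indices into risk-table intervals [t_i, t_{i+1}).

    Returns one ``(start, stop)`` index range per interval (left-closed
    binning; the last interval is open-ended to the last click). Risk-table
    boundaries beyond the last click are dropped. Empty intervals are
    allowed.
    """
    curve.validate()
    if np.any(curve.times < 0):
        raise ValidationError("click before time 0")
    boundaries = risk.times[risk.times <= curve.times[-1] + 1e-9]
    if len(boundaries) == 0:
        boundaries = risk.times[:1]
    idx = np.searchsorted(boundaries, curve.times, side="right") - 1
    if np.any(idx < 0):
        raise ValidationError("click before the first risk-table time")
    ranges = []
    for i in range(len(boundaries)):
        members = np.flatnonzero(idx == i)
        if len(members):
            ranges.append((int(members[0]), int(members[-1]) + 1))
        else:
            ranges.append((0, 0) if not ranges else (ranges[-1][1], ranges[-1][1]))
    return ranges


def _censor_times(t_start: float, t_end: float, c: int) -> np.ndarray:
    """c censoring times uniformly spaced at positions (j - 0.5)/c of the interval."""
    if c <= 0:
        return np.empty(0)
    if t_end <= t_start:
        return np.full(c, t_start)
    return t_start + (np.arange(1, c + 1) - 0.5) / c * (t_end - t_start)


def _walk_interval(
    click_t: np.ndarray,
    click_s: np.ndarray,
    t_start: float,
    t_end: float,
    c: int,
    n_in: int,
    s_in: float,
):
    """Allocate events/censorings over one interval for censoring count c.

    Clicks and the c uniformly spaced censorings are processed in time
    order (events before censorings at ties). Returns
    (n_out, s_out, events, censor_times_used).
    """
    cens = _censor_times(t_start, t_end, c)
    # merge: kind 0 = click, 1 = censor; clicks first on time ties
    items = sorted(
        [(float(t), 0, float(s)) for t, s in zip(click_t, click_s)]
        + [(float(t), 1, 0.0) for t in cens]
    )
    n, S = int(n_in), float(s_in)
    events: list[tuple[float, int]] = []
    used_cens: list[float] = []
    for t, kind, s in items:
        if kind == 0:
            if n <= 0 or S <= 0:
                continue
            d_frac = n * (1.0 - s / S)
            d = int(np.floor(d_frac + 0.5))
            d = max(0, min(d, n))
            if d > 0:
                S *= 1.0 - d / n
                n -= d
                events.append((t, d))
        else:
            if n > 0:
                n -= 1
                used_cens.append(t)
    return n, S, events, used_cens


def _solve_censoring(click_t, click_s, t_start, t_end, n_in, s_in, target_n):
    """Monotone integer bisection over the interval censoring count.

    Finds c in [0, n_in] whose implied at-risk count at the interval end
    matches ``target_n``; ties (equal mismatch) break toward fewer
    censorings. Returns (c, walk_result, matched_exactly).
    """

    def f(c):
        res = _walk_interval(click_t, click_s, t_start, t_end, c, n_in, s_in)
        return res[0] - target_n, res

    f0, res0 = f(0)
    if f0 <= 0:
        return 0, res0, f0 == 0
    lo, flo = 0, f0
    hi = n_in
    fhi, reshi = f(hi)
    if fhi > 0:
        return hi, reshi, False
    while hi - lo > 1:
        mid = (lo + hi) // 2
        fm, resm = f(mid)
        if fm > 0:
            lo, flo = mid, fm
        else:
            hi, fhi, reshi = mid, fm, resm
    if fhi == 0:
        return hi, reshi, True
    # neither candidate exact: pick the smaller absolute mismatch, fewer censorings on ties
    _, reslo = f(lo)
    if abs(flo) <= abs(fhi):
        return lo, reslo, False
    return hi, reshi, False


def reconstruct_ipd(
    curve: DigitizedCurve,
    risk: RiskTable,
    total_events: Optional[int] = None,
) -> tuple[pd.DataFrame, ReconstructionReport]:
    """Reconstruct an IPD table for one arm from clicks + risk table.

    The output always contains exactly ``risk.n_risk[0]`` records; events
    plus censorings conserve the arm size. Patients still at risk after the
    last click are censored there (administrative censoring). If
    ``total_events`` is given (falling back to ``risk.total_events``), the
    final interval is rebalanced so the reconstructed event total matches
    it exactly when feasible.
    """
    curve.validate()
    if risk.n_risk[0] < 2:
        raise ValidationError("risk table must start with at least 2 patients")
    if total_events is None:
        total_events = risk.total_events

    last_t = float(curve.times[-1])
    keep = risk.times <= last_t + 1e-9
    btimes = risk.times[keep]
    bn = risk.n_risk[keep]
    if len(btimes) == 0:
        btimes, bn = risk.times[:1], risk.n_risk[:1]
    ranges = assign_intervals(curve, RiskTable(risk.trial_id, risk.arm, btimes, bn))

    n = int(bn[0])
    S = 1.0
    all_events: list[tuple[float, int]] = []
    all_cens: list[float] = []
    risk_match: list[tuple[int, int]] = []
    converged = True
    final_interval_start = len(all_events)

    for i in range(len(btimes)):
        t_start = float(btimes[i])
        t_end = float(btimes[i + 1]) if i + 1 < len(btimes) else last_t
        lo_idx, hi_idx = ranges[i]
        ct = curve.times[lo_idx:hi_idx]
        cs = curve.survival[lo_idx:hi_idx]
        interior = i + 1 < len(btimes)
        if interior:
            target = int(bn[i + 1])
            if n <= 0 < target:
                raise ReconstructionInfeasibleError(
                    f"interval {i}: no patients left at risk but published n_risk is {target}"
                )
            c, (n_out, s_out, events, cens), exact = _solve_censoring(
                ct, cs, t_start, t_end, n, S, target
            )
            converged = converged and exact
            risk_match.append((target, int(n_out)))
        else:
            final_interval_start = len(all_events)
            n_out, s_out, events, cens = _walk_interval(ct, cs, t_start, t_end, 0, n, S)
        all_events.extend(events)
        all_cens.extend(cens)
        n, S = n_out, s_out

    # administrative censoring of everyone still at risk at the last click
    end_censored = n
    all_cens.extend([last_t] * end_censored)
    n = 0

    if total_events is not None:
        tot_d = sum(d for _, d in all_events)
        delta = int(total_events) - tot_d
        if delta > 0:
            move = min(delta, end_censored)
            if move:
                del all_cens[len(all_cens) - move:]
                all_events.append((last_t, move))
        elif delta < 0:
            need = -delta
            for j in range(len(all_events) - 1, final_interval_start - 1, -1):
                if need == 0:
                    break
                t_j, d_j = all_events[j]
                take = min(d_j, need)
                all_events[j] = (t_j, d_j - take)
                all_cens.extend([t_j] * take)
                need -= take
            all_events = [(t, d) for t, d in all_events if d > 0]

    times = [t for t, d in all_events for _ in range(d)] + list(all_cens)
    events_flag = [1] * sum(d for _, d in all_events) + [0] * len(all_cens)
    ipd = make_ipd(times, events_flag, arm=curve.arm, trial_id=curve.trial_id)
    ipd = ipd.sort_values(["time", "event"], ascending=[True, False]).reset_index(drop=True)
    ipd = validate_ipd(ipd)

    km = kaplan_meier(ipd)
    rep = fidelity(curve, km)
    rep.risk_match = risk_match
    rep.converged = converged
    return ipd, rep


def fidelity(curve: DigitizedCurve, reconstructed_km: KMEstimate) -> ReconstructionReport:
    """Max absolute deviation and RMSE between clicks and a KM re-estimate.

    The KM estimate is evaluated at the click times as a right-continuous
    step function and compared with the click survival values.
    """
    shat = reconstructed_km.survival_at(curve.times)
    dev = np.abs(curve.survival - shat)
    n_ev = int(reconstructed_km.n_events_at.sum())
    return ReconstructionReport(
        max_abs_dev=float(dev.max()),
        rmse=float(np.sqrt(np.mean(dev**2))),
        n_events_reconstructed=n_ev,
        n_censored_reconstructed=int(reconstructed_km.n_total - n_ev),
    )
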