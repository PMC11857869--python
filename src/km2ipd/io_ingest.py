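"""Ingestion of digitizer output, risk tables and IPD files.

A published Kaplan-Meier figure yields two machine-readable artifacts: the
curve itself, exported by a point-and-click digitizer as an ordered list of
(time, survival) coordinates ("clicks"), and the numbers-at-risk row printed
beneath the plot. This module turns both into validated domain objects,
cleans digitizer jitter (a KM estimate is non-increasing by construction,
digitized clicks often are not), and reads/writes the flat IPD table
(time, event, arm, trial_id) that the rest of the package consumes.

Times are in months throughout; survival is a probability in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .errors import InsufficientDataError, ParseError, ValidationError

IPD_COLUMNS = ["time", "event", "arm", "trial_id"]


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered survival-curve clicks for one arm of one trial."""

    trial_id: str
    arm: str
    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        if self.times.shape != self.survival.shape or self.times.ndim != 1:
            raise ValidationError("times and survival must be 1-d arrays of equal length")

    @property
    def clicks(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.survival.tolist()))

    def __len__(self) -> int:
        return len(self.times)

    def validate(self) -> None:
        """Check the sanitized-curve invariants; raise ValidationError otherwise."""
        if len(self) < 2:
            raise ValidationError("curve needs at least 2 clicks")
        if np.any(self.times < 0):
            raise ValidationError("click times must be >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("click times must be strictly increasing")
        if self.survival[0] > 1.0:
            raise ValidationError("first click survival must be <= 1")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValidationError("survival must be non-increasing (run sanitize_monotone)")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValidationError("survival values must lie in [0, 1]")


@dataclass(frozen=True)
class RiskTable:
    """Published numbers at risk at interval boundaries, plus optional event total."""

    trial_id: str
    arm: str
    times: np.ndarray
    n_risk: np.ndarray
    total_events: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        n = np.asarray(self.n_risk)
        if n.size and not np.all(n == np.floor(n)):
            raise ValidationError("n_risk must be integers")
        object.__setattr__(self, "n_risk", n.astype(int))
        if self.times.shape != self.n_risk.shape or self.times.ndim != 1:
            raise ValidationError("times and n_risk must be 1-d arrays of equal length")
        if self.times.size == 0:
            raise ValidationError("risk table is empty")
        if self.times[0] != 0:
            raise ValidationError("risk table must start at time 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("risk-table times must be strictly increasing")
        if np.any(self.n_risk <= 0):
            raise ValidationError("n_risk entries must be positive")
        if np.any(np.diff(self.n_risk) > 0):
            raise ValidationError("n_risk must be non-increasing")
        if self.total_events is not None and self.total_events < 0:
            raise ValidationError("total_events must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis settings: truncation time tau, NI margin, CI levels, reference arm.

    ``margin`` is the largest tolerated loss in event-free months over
    [0, tau]; positive by convention.
    """

    tau: float = 30.0
    margin: float = 2.0
    ci_level_main: float = 0.95
    ci_level_ni: float = 0.90
    reference_arm: str = "warfarin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.margin <= 0:
            raise ValidationError("margin must be positive")
        for lvl in (self.ci_level_main, self.ci_level_ni):
            if not 0 < lvl < 1:
                raise ValidationError("CI levels must be in (0, 1)")


def load_config(path) -> AnalysisConfig:
    """Load an AnalysisConfig from a JSON file; missing keys take defaults."""
    with open(path) as fh:
        raw = json.load(fh)
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def _two_numeric_columns(path, header: bool) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, header=0 if header else None)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected at least two columns")
    x = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    y = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = (x.isna() | y.isna()).to_numpy()
    if bad.any():
        row = int(np.argmax(bad)) + 1  # 1-based data row
        raise ParseError(f"{path}: non-numeric cell in data row {row}")
    return x.to_numpy(float), y.to_numpy(float)


def read_curve_csv(
    path,
    trial_id: str,
    arm: str,
    survival_scale: str = "probability",
    header: bool = True,
) -> DigitizedCurve:
    """Read a digitizer-export CSV of (time, survival) clicks.

    Rows may be unsorted and noisy. Percent-scale survival is divided by
    100; values are clamped to [0, 1]; rows sharing a time collapse to the
    lowest survival (the bottom of a vertical drop digitized twice). The
    result is NOT yet monotone -- pass it through :func:`sanitize_monotone`.
    """
    if survival_scale not in ("probability", "percent"):
        raise ValueError("survival_scale must be 'probability' or 'percent'")
    t, s = _two_numeric_columns(path, header)
    if survival_scale == "percent":
        s = s / 100.0
    s = np.clip(s, 0.0, 1.0)
    order = np.argsort(t, kind="stable")
    t, s = t[order], s[order]
    # collapse duplicate times, keeping the minimum survival
    ut, inverse = np.unique(t, return_inverse=True)
    us = np.full(ut.shape, np.inf)
    np.minimum.at(us, inverse, s)
    if len(ut) < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 usable clicks")
    return DigitizedCurve(trial_id=trial_id, arm=arm, times=ut, survival=us)


def sanitize_monotone(curve: DigitizedCurve) -> DigitizedCurve:
    """Project click survival onto the best non-increasing sequence (least squares).

    Pool-adjacent-violators via sklearn's isotonic regression with
    ``increasing=False``; times are unchanged. Identity on already-monotone
    input, hence idempotent. Output is clamped to [0, 1].
    """
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    fitted = iso.fit_transform(curve.times, curve.survival)
    fitted = np.clip(fitted, 0.0, 1.0)
    # enforce exact monotonicity against floating fuzz
    fitted = np.minimum.accumulate(fitted)
    out = replace(curve, survival=fitted)
    out.validate()
    return out


def read_risk_csv(
    path,
    trial_id: str,
    arm: str,
    total_events: Optional[int] = None,
    header: bool = True,
) -> RiskTable:
    """Read a (time, n_risk) CSV into a validated RiskTable."""
    t, n = _two_numeric_columns(path, header)
    order = np.argsort(t, kind="stable")
    return RiskTable(
        trial_id=trial_id, arm=arm, times=t[order], n_risk=n[order],
        total_events=total_events,
    )


def validate_ipd(ipd: pd.DataFrame) -> pd.DataFrame:
    """Validate an IPD table; returns it with normalized dtypes."""
    missing = [c for c in IPD_COLUMNS if c not in ipd.columns]
    if missing:
        raise ValidationError(f"IPD table missing columns: {missing}")
    out = ipd.loc[:, IPD_COLUMNS].copy()
    time = pd.to_numeric(out["time"], errors="coerce")
    if time.isna().any():
        row = int(np.argmax(time.isna().to_numpy())) + 1
        raise ValidationError(f"non-numeric time in row {row}")
    if (time < 0).any():
        row = int(np.argmax((time < 0).to_numpy())) + 1
        raise ValidationError(f"negative time in row {row}")
    event = pd.to_numeric(out["event"], errors="coerce")
    bad = ~event.isin([0, 1])
    if bad.any():
        row = int(np.argmax(bad.to_numpy())) + 1
        raise ValidationError(f"event value outside {{0,1}} in row {row}")
    out["time"] = time.astype(float)
    out["event"] = event.astype(int)
    out["arm"] = out["arm"].astype(str)
    out["trial_id"] = out["trial_id"].astype(str)
    return out.reset_index(drop=True)


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    """Write an IPD table (columns time, event, arm, trial_id) to CSV."""
    validate_ipd(ipd).to_csv(path, index=False)


def read_ipd_csv(path) -> pd.DataFrame:
    """Read and validate an IPD CSV written by :func:`write_ipd_csv`."""
    return validate_ipd(pd.read_csv(path))


def make_ipd(
    times: Sequence[float],
    events: Sequence[int],
    arm: str = "arm",
    trial_id: str = "trial",
) -> pd.DataFrame:
    """Convenience constructor for a single-arm IPD table."""
    df = pd.DataFrame(
        {"time": list(times), "event": list(events), "arm": arm, "trial_id": trial_id}
    )
    return validate_ipd(df)
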