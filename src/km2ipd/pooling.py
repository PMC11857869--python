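"""Pooling reconstructed per-trial IPD into per-treatment datasets.

All patients who received the same treatment across trials are combined
into a single group (hence a single pooled KM curve per treatment). A
TrialArmMap translates each trial's local arm label (e.g. "device",
"control") into a canonical treatment label; trial identity is retained on
every record so stratified analyses remain possible downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_ingest import validate_ipd
from .survstats import cox_fit


@dataclass(frozen=True)
class TrialArmMap:
    """(trial_id, source arm) -> canonical treatment label."""

    entries: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        keys = [(t, a) for t, a, _ in self.entries]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValidationError(f"duplicate (trial, arm) entries in map: {sorted(dupes)}")

    @classmethod
    def from_csv(cls, path) -> "TrialArmMap":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        try:
            entries = tuple((r["trial_id"], r["arm"], r["treatment"]) for r in rows)
        except KeyError as exc:
            raise ValidationError(f"map CSV needs columns trial_id, arm, treatment: {exc}")
        return cls(entries)

    @property
    def treatments(self) -> list[str]:
        return sorted({t for _, _, t in self.entries})

    def treatment_for(self, trial_id: str, arm: str) -> str:
        for t, a, label in self.entries:
            if t == trial_id and a == arm:
                return label
        raise ValidationError(f"unmapped (trial, arm) pair: ({trial_id!r}, {arm!r})")


def pool_arms(datasets: Sequence[pd.DataFrame], arm_map: TrialArmMap) -> pd.DataFrame:
    """Concatenate per-trial IPD, replacing arm labels with canonical treatments.

    Record count is conserved; every record keeps its trial_id. An input
    (trial, arm) pair absent from the map raises, naming the pair.
    """
    parts = []
    for ds in datasets:
        ds = validate_ipd(ds)
        labels = [
            arm_map.treatment_for(t, a)
            for t, a in zip(ds["trial_id"], ds["arm"])
        ]
        out = ds.copy()
        out["arm"] = labels
        parts.append(out)
    return pd.concat(parts, ignore_index=True)


def heterogeneity(
    ipd: pd.DataFrame,
    mode: str = "treatment_factor",
    reference_arm: str | None = None,
) -> dict:
    """Heterogeneity / treatment-effect diagnostics on pooled IPD.

    ``treatment_factor``: LRT and Wald statistics of the pooled Cox
    treatment factor against the null model (df = arms - 1).
    ``trial_strata``: a crude between-trial diagnostic, 2 * (partial
    log-likelihood of the trial-stratified fit minus the unstratified fit),
    clamped at 0, on df = trials - 1; the Wald statistic reported alongside
    is the stratified fit's treatment-factor Wald test.

    Returns ``{"lrt": (stat, df, p), "wald": (stat, df, p)}``.
    """
    ipd = validate_ipd(ipd)
    if reference_arm is None:
        reference_arm = sorted(ipd["arm"].unique())[0]
    if mode == "treatment_factor":
        fit = cox_fit(ipd, reference_arm)
        return {
            "lrt": (fit.lrt_stat, fit.lrt_df, fit.lrt_p),
            "wald": (fit.wald_stat, fit.lrt_df, fit.wald_p),
        }
    if mode == "trial_strata":
        n_trials = ipd["trial_id"].nunique()
        if n_trials < 2:
            raise ValidationError("trial_strata mode needs >= 2 trials")
        unstrat = cox_fit(ipd, reference_arm)
        strat = cox_fit(ipd, reference_arm, strata=True)
        stat = max(0.0, 2.0 * (strat.log_likelihood - unstrat.log_likelihood))
        df = n_trials - 1
        p = float(stats.chi2.sf(stat, df))
        return {
            "lrt": (stat, df, p),
            "wald": (strat.wald_stat, strat.lrt_df, strat.wald_p),
        }
    raise ValueError("mode must be 'treatment_factor' or 'trial_strata'")
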