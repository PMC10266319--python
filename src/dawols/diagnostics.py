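"""Model-fitness battery: in-sample RMSE/MAE over draws, predicted-vs-observed
group-mean gaps, graphical/numeric predictive checks, and an empirical
proportional-odds diagnostic.

Predictions entering RMSE/MAE are patient-level *expected* means (clamped to
the outcome space, on the days scale), not predictive draws: comparing
expected values against the data is what makes the error measures nearly
identical across families whose predictive distributions differ wildly.
Evaluation is in-sample by design (the question is how well each model
describes the data it was fitted to); a holdout set can be passed explicitly
via ``data`` if out-of-sample behaviour is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimands import patient_expected_days, summarize_draws
from .models import BaseOutcomeModel, sample_predictive
from .outcome import DataError, OutcomeSpec, arms as arm_levels


def _observed_days(fit, data, spec) -> np.ndarray:
    """Observed outcomes on the days scale (deaths coded 0, -1 mapped to 0)."""
    y = np.asarray(data["outcome"], dtype=float)
    if fit.family == "zoib":
        y = y * spec.max_days
    return np.where(y == -1.0, 0.0, y)


def rmse_draws(fit: BaseOutcomeModel, data: pd.DataFrame, spec: OutcomeSpec,
               variant: str = "minus_one_as_zero") -> np.ndarray:
    """Per-draw root mean squared error of expected predictions (days scale)."""
    y = _observed_days(fit, data, spec)
    pred = patient_expected_days(fit, spec, data, variant)
    return np.sqrt(np.mean((pred - y[None, :]) ** 2, axis=1))


def mae_draws(fit: BaseOutcomeModel, data: pd.DataFrame, spec: OutcomeSpec,
              variant: str = "minus_one_as_zero") -> np.ndarray:
    """Per-draw median absolute error of expected predictions (days scale)."""
    y = _observed_days(fit, data, spec)
    pred = patient_expected_days(fit, spec, data, variant)
    return np.median(np.abs(pred - y[None, :]), axis=1)


def mean_gap_draws(fit: BaseOutcomeModel, data: pd.DataFrame, spec: OutcomeSpec,
                   arm: str, variant: str = "minus_one_as_zero") -> np.ndarray:
    """Per-draw (predicted arm mean) - (observed arm mean), days scale."""
    sel = data["arm"] == arm
    if not sel.any():
        raise DataError(f"arm {arm!r} not present")
    sub = data[sel]
    y = _observed_days(fit, sub, spec)
    pred = patient_expected_days(fit, spec, sub, variant)
    return pred.mean(axis=1) - y.mean()


def fitness_report(fits: dict[str, BaseOutcomeModel], spec: OutcomeSpec,
                   datasets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Model-comparison rows: RMSE, MAE and per-arm mean gaps, each as
    median (95% percentile interval) over draws. Cumulative-logit fits with a
    -1 death category get one row per death-code variant."""
    rows = []
    for label, fit in fits.items():
        data = datasets[label]
        variants = ("minus_one_as_zero", "minus_one_as_is") \
            if fit.family == "cumlogit" and -1 in fit.value_map_ else ("minus_one_as_zero",)
        for variant in variants:
            row_label = label if len(variants) == 1 else f"{label} ({variant})"
            row = {"model": row_label, "family": fit.family, "variant": variant}
            for name, fn in (("rmse", rmse_draws), ("mae", mae_draws)):
                med, lo, hi = summarize_draws(fn(fit, data, spec, variant))
                row[name] = med
                row[f"{name}_ci"] = (lo, hi)
            for arm in arm_levels(data):
                med, lo, hi = summarize_draws(
                    mean_gap_draws(fit, data, spec, arm, variant))
                row[f"mean_gap_{arm}"] = med
                row[f"mean_gap_{arm}_ci"] = (lo, hi)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# predictive checks


@dataclass
class PredictiveCheck:
    """Replicated-data check for one arm.

    ``grid`` spans the integer outcome space; ``observed_hist`` and
    ``replicate_hists`` (shape ``(n_rep, len(grid))``) are proportions.
    ``tv_observed[r]`` is the total-variation distance between replicate r and
    the observed histogram; ``tv_replicates`` holds distances between random
    replicate pairs, whose central 95% range is the calibration band.
    """

    arm: str
    grid: np.ndarray
    observed_hist: np.ndarray
    replicate_hists: np.ndarray
    replicate_means: np.ndarray
    tv_observed: np.ndarray
    tv_replicates: np.ndarray
    prop_min: np.ndarray
    prop_max: np.ndarray
    observed_prop_min: float
    observed_prop_max: float

    def tv_calibration_band(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.tv_replicates, [2.5, 97.5])
        return float(lo), float(hi)

    def observed_inside_band(self) -> bool:
        lo, hi = self.tv_calibration_band()
        return bool(lo <= np.median(self.tv_observed) <= hi)

    def tidy(self) -> pd.DataFrame:
        rows = [{"arm": self.arm, "replicate": -1, "value": v, "proportion": p}
                for v, p in zip(self.grid, self.observed_hist)]
        for r in range(len(self.replicate_hists)):
            rows += [{"arm": self.arm, "replicate": r, "value": v, "proportion": p}
                     for v, p in zip(self.grid, self.replicate_hists[r])]
        return pd.DataFrame(rows)


def _tv(p, q):
    return 0.5 * np.abs(p - q).sum(axis=-1)


def predictive_check(fit: BaseOutcomeModel, data: pd.DataFrame, spec: OutcomeSpec,
                     n_rep: int = 100, seed=None) -> dict[str, PredictiveCheck]:
    """Per-arm replicated-outcome check against the observed distribution.

    Replicates are sampled from the fitted model (one parameter draw per
    replicate), clamped to the outcome space and rounded to the integer day
    grid so that continuous families are comparable with count data. The
    discrepancy score is the total-variation distance between the replicate
    and observed value histograms.
    """
    rng = np.random.default_rng(seed)
    lo = -1 if (fit.family == "cumlogit" and -1 in getattr(fit, "value_map_", [])) else 0
    grid = np.arange(lo, spec.max_days + 1)
    out = {}
    for arm in arm_levels(data):
        sub = data[data["arm"] == arm]
        y_obs = _observed_days(fit, sub, spec)
        if lo == -1:  # keep the death category visible on the ordinal grid
            y_obs = np.asarray(sub["outcome"], dtype=float)
        raw, clamped = sample_predictive(
            fit, sub, n_rep, seed=rng.integers(2**31), max_days=spec.max_days)
        reps = np.clip(np.round(clamped), lo, spec.max_days).astype(int)
        rep_hists = np.stack([
            np.bincount(r - lo, minlength=len(grid)) / len(r) for r in reps
        ])
        y_grid = np.clip(np.round(y_obs).astype(int), lo, spec.max_days)
        obs_hist = np.bincount(y_grid - lo, minlength=len(grid)) / len(y_obs)
        tv_obs = _tv(rep_hists, obs_hist[None, :])
        perm = rng.permutation(n_rep)
        tv_reps = _tv(rep_hists, rep_hists[perm]) if n_rep > 1 else np.zeros(1)
        out[arm] = PredictiveCheck(
            arm=arm, grid=grid, observed_hist=obs_hist, replicate_hists=rep_hists,
            replicate_means=clamped.mean(axis=1), tv_observed=tv_obs,
            tv_replicates=tv_reps,
            prop_min=(reps == grid[0]).mean(axis=1),
            prop_max=(reps == spec.max_days).mean(axis=1),
            observed_prop_min=float((y_obs == grid[0]).mean()),
            observed_prop_max=float((y_obs == spec.max_days).mean()),
        )
    return out


def proportional_odds_check(data: pd.DataFrame, arm_pair=None) -> pd.DataFrame:
    """Empirical per-cutpoint cumulative log odds ratios.

    For each cutpoint k over the sorted distinct outcome values:
    ``log odds(Y <= k | control) - log odds(Y <= k | intervention)``, with the
    Haldane-Anscombe 0.5 correction guarding empty cells. Under proportional
    odds the profile is constant (at the log cumulative OR); trends or sign
    changes indicate violation — the classic pattern is a treatment whose
    mortality effect opposes its effect on survivor days.
    """
    levels = arm_levels(data)
    if arm_pair is None:
        if len(levels) != 2:
            raise DataError("arm_pair required with more than two arms")
        arm_pair = (levels[0], levels[1])
    control, interv = arm_pair
    if control == interv or control not in levels or interv not in levels:
        raise DataError(f"invalid arm pair {arm_pair}")
    values = np.sort(data["outcome"].unique())
    if len(values) < 3:
        raise DataError("need at least 3 distinct outcome values")
    y_c = np.asarray(data.loc[data["arm"] == control, "outcome"], dtype=float)
    y_i = np.asarray(data.loc[data["arm"] == interv, "outcome"], dtype=float)
    rows = []
    for v in values[:-1]:  # last cutpoint is degenerate (everything <= max)
        a, b = (y_c <= v).sum() + 0.5, (y_c > v).sum() + 0.5
        c, d = (y_i <= v).sum() + 0.5, (y_i > v).sum() + 0.5
        rows.append({"cutpoint_value": v,
                     "log_cum_or": float(np.log(a / b) - np.log(c / d))})
    return pd.DataFrame(rows)
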