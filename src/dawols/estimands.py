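"""Common estimands across models: group mean days, mean difference, ratio of
means, and the cumulative odds ratio, each summarised as the draw median with
a 95% percentile interval.

Every family is reduced to the same quantity — the expected mean outcome on
the days scale per arm, per draw — so that families as different as a
Gaussian mean and an ordinal category distribution can be compared head to
head. Sub-model predictions are combined per family (hurdle: ``(1 - pi) *``
truncated-NB mean; ZOIB: mixture mean times ``max_days``; cumulative logit:
category probabilities times category values, summed), truncated to the valid
outcome space at the patient level, and averaged within arm. With covariates
in the model the group means are marginal (standardised): patient-level
predictions are averaged over the pooled analysis set with every patient's
arm set to the target level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import BaseOutcomeModel, CumulativeLogit
from .outcome import ConfigError, DataError, OutcomeSpec, arms as arm_levels

VARIANTS = ("minus_one_as_zero", "minus_one_as_is")


def summarize_draws(draws) -> tuple[float, float, float]:
    """Median and 2.5/97.5 percentiles (linear-interpolation quantiles).

    The percentile rule is numpy's ``linear`` definition, applied uniformly
    to every interval this package reports.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise DataError("summarize_draws needs at least one draw")
    med = float(np.median(draws))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return med, float(lo), float(hi)


def truncate_to_valid(values, spec: OutcomeSpec, variant: str = "minus_one_as_zero"):
    """Clamp predictions to the outcome space.

    ``[0, max_days]`` in general; the ``minus_one_as_is`` cumulative-logit
    variant keeps the death category at -1, widening the space to
    ``[-1, max_days]``.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}")
    lo = -1.0 if variant == "minus_one_as_is" else 0.0
    return np.clip(np.asarray(values, dtype=float), lo, spec.max_days)


@dataclass
class GroupMeans:
    """Per-arm vectors (over draws) of expected mean outcome on the days scale."""

    draws: dict[str, np.ndarray]
    variant: str
    truncated: bool
    max_days: int

    @property
    def arms(self) -> list[str]:
        return list(self.draws)

    def summary(self) -> pd.DataFrame:
        rows = []
        for arm, d in self.draws.items():
            med, lo, hi = summarize_draws(d)
            rows.append({"arm": arm, "median": med, "lower95": lo, "upper95": hi})
        return pd.DataFrame(rows)


@dataclass
class EffectEstimate:
    estimand: str
    contrast: tuple[str, str]  # (intervention, control)
    median: float
    lower95: float
    upper95: float
    draws: np.ndarray

    def __str__(self):
        a, c = self.contrast
        return (f"{self.estimand}[{a} vs {c}]: "
                f"{self.median:.2f} ({self.lower95:.2f} to {self.upper95:.2f})")


def patient_expected_days(fit: BaseOutcomeModel, spec: OutcomeSpec,
                          data: pd.DataFrame, variant: str = "minus_one_as_zero",
                          point: bool = False) -> np.ndarray:
    """Patient-level expected outcomes on the days scale, clamped.

    Returns shape ``(D, n)`` over draws (or ``(n,)`` at the MLE when
    ``point``). ZOIB proportions are rescaled by ``max_days``; the
    cumulative-logit death category enters the weighted value sum as 0
    (``minus_one_as_zero``) or as -1 (``minus_one_as_is``).
    """
    if isinstance(fit, CumulativeLogit):
        values = np.asarray(fit.value_map_, dtype=float)
        if variant == "minus_one_as_zero":
            values = np.where(values == -1.0, 0.0, values)
        if point:
            pred = fit._expected(fit._matrices(data), fit.point_, values=values)
        else:
            pred = fit.expected_draws(data, values=values)
    else:
        if point:
            pred = fit.predict(data)
        else:
            pred = fit.expected_draws(data)
        if fit.family == "zoib":
            pred = pred * spec.max_days
    return truncate_to_valid(pred, spec, variant)


def expected_mean(fit: BaseOutcomeModel, spec: OutcomeSpec, data: pd.DataFrame,
                  variant: str = "minus_one_as_zero", marginal: bool = True) -> GroupMeans:
    """Per-arm expected mean outcome per draw (days scale).

    With ``marginal`` (default) each arm's mean standardises over the pooled
    analysis set: every patient's ``arm`` is set to the target level and
    patient-level clamped predictions are averaged. Without covariates this
    reduces to the fitted arm means. ``marginal=False`` averages each arm's
    own patients at their observed covariate values (conditional-on-arm
    sample mean of predictions).
    """
    levels = arm_levels(data)
    out: dict[str, np.ndarray] = {}
    for arm in levels:
        if marginal:
            newdata = data.copy()
            newdata["arm"] = pd.Categorical(
                [arm] * len(data), categories=data["arm"].cat.categories, ordered=True
            )
        else:
            newdata = data[data["arm"] == arm]
        pred = patient_expected_days(fit, spec, newdata, variant)
        out[arm] = pred.mean(axis=1)
    return GroupMeans(draws=out, variant=variant, truncated=True, max_days=spec.max_days)


def _resolve_contrast(gm_arms: list[str], contrast) -> tuple[str, str]:
    if contrast is None:
        if len(gm_arms) != 2:
            raise ConfigError("contrast required when more than two arms are present")
        return gm_arms[1], gm_arms[0]
    interv, control = contrast
    for a in (interv, control):
        if a not in gm_arms:
            raise DataError(f"arm {a!r} not present")
    return interv, control


def mean_difference(gm: GroupMeans, contrast: tuple[str, str] | None = None) -> EffectEstimate:
    """Per-draw difference in expected means, intervention minus control."""
    interv, control = _resolve_contrast(gm.arms, contrast)
    d = gm.draws[interv] - gm.draws[control]
    med, lo, hi = summarize_draws(d)
    return EffectEstimate("mean_difference", (interv, control), med, lo, hi, d)


def ratio_of_means(gm: GroupMeans, contrast: tuple[str, str] | None = None,
                   max_excluded_frac: float = 0.01) -> EffectEstimate:
    """Per-draw ratio of expected means, intervention over control.

    Draws with a non-positive control mean are excluded with a warning; more
    than ``max_excluded_frac`` of them is an error.
    """
    interv, control = _resolve_contrast(gm.arms, contrast)
    c = gm.draws[control]
    ok = c > 0
    n_bad = int((~ok).sum())
    if n_bad:
        if n_bad > max_excluded_frac * len(c):
            raise DataError(
                f"{n_bad}/{len(c)} draws have non-positive control mean; "
                "ratio of means is not identifiable"
            )
        warnings.warn(f"excluded {n_bad} draws with non-positive control mean "
                      "from the ratio of means", stacklevel=2)
    r = gm.draws[interv][ok] / c[ok]
    med, lo, hi = summarize_draws(r)
    return EffectEstimate("ratio_of_means", (interv, control), med, lo, hi, r)


def all_contrasts(gm: GroupMeans, estimand=mean_difference) -> list[EffectEstimate]:
    """One effect estimate per non-control arm versus the control (first) arm."""
    control = gm.arms[0]
    return [estimand(gm, (arm, control)) for arm in gm.arms[1:]]


def cumulative_odds_ratio(fit: CumulativeLogit,
                          contrast: tuple[str, str] | None = None) -> EffectEstimate:
    """Cumulative OR: exp of the arm coefficient, per draw.

    Oriented as the odds of a *higher* (better) outcome category for the
    intervention relative to the control arm; OR > 1 favours the
    intervention.
    """
    if getattr(fit, "family", None) != "cumlogit":
        raise ConfigError("cumulative_odds_ratio requires a cumulative-logit fit")
    arm_cats = list(fit.design_.levels["arm"])
    interv, control = _resolve_contrast(arm_cats, contrast)
    if control != arm_cats[0]:
        raise ConfigError("cumulative OR is parameterised against the control "
                          f"(first) arm {arm_cats[0]!r}")
    name = f"beta__arm[{interv}]"
    j = fit.param_names_.index(name)
    d = np.exp(fit.draws_[:, j])
    med, lo, hi = summarize_draws(d)
    return EffectEstimate("cumulative_or", (interv, control), med, lo, hi, d)


def estimand_report(fits: dict[str, BaseOutcomeModel], spec: OutcomeSpec,
                    datasets: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble a model-comparison table of group means, MD and RoM.

    ``fits`` maps a row label to a fitted model; ``datasets`` maps the same
    labels to the trial table each model was fitted on (families use
    different outcome scales). Cumulative-logit fits contribute two rows, one
    per death-code variant, plus the cumulative OR.
    """
    rows = []
    for label, fit in fits.items():
        data = datasets[label]
        variants = VARIANTS if fit.family == "cumlogit" and -1 in fit.value_map_ \
            else ("minus_one_as_zero",)
        for variant in variants:
            gm = expected_mean(fit, spec, data, variant=variant)
            row_label = label if len(variants) == 1 else f"{label} ({variant})"
            row = {"model": row_label, "family": fit.family, "variant": variant}
            for arm, dr in gm.draws.items():
                med, lo, hi = summarize_draws(dr)
                row[f"mean_{arm}"] = med
                row[f"mean_{arm}_ci"] = (lo, hi)
            md = mean_difference(gm)
            rom = ratio_of_means(gm)
            row.update(md_median=md.median, md_ci=(md.lower95, md.upper95),
                       rom_median=rom.median, rom_ci=(rom.lower95, rom.upper95))
            if fit.family == "cumlogit":
                cor = cumulative_odds_ratio(fit)
                row.update(cum_or_median=cor.median,
                           cum_or_ci=(cor.lower95, cor.upper95))
            rows.append(row)
    return pd.DataFrame(rows)
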