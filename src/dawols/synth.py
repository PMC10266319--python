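"""Seeded generator of synthetic multi-arm trials with DAWOLS-shaped outcomes.

Real DAWOLS distributions are heavily inflated at the minimum (non-survivors
penalised to the worst value), often inflated at the maximum (patients who
never needed life support within a short follow-up) and skewed in between.
The generator reproduces that three-component mixture per arm:

1. death with probability ``p_death`` (outcome 0 / -1 / actual per spec);
2. among survivors, the maximum value ``max_days`` with probability ``p_max``
   (never on life support);
3. remaining survivors draw their free days from a negative binomial with
   mean ``interior_mean`` and dispersion ``interior_dispersion``, truncated
   to {1, ..., max_days - 1}.

The interior is negative-binomial so the hurdle-NB family is correctly
specified in at least one scenario; proportional-odds-consistent ordinal data
are generated separately by :func:`simulate_proportional_odds` since the
mixture above deliberately violates proportional odds when arm effects on
mortality and survivor days differ.

Each arm draws from its own child RNG stream keyed by the arm name, so adding
an arm to a scenario map never perturbs the other arms' draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit, logit

from .outcome import ConfigError, OutcomeSpec, validate_trial_table

#: default arm scenarios emulating a two-arm ICU trial of ~970 patients with
#: 28-day follow-up: ~30% mortality, a substantial spike at 28 days and a
#: right-skewed interior. These are the package's standard study conditions.
COVID_LIKE = None  # assigned below, after ArmScenario is defined


@dataclass(frozen=True)
class ArmScenario:
    """Generative description of one arm's outcome distribution.

    Parameters
    ----------
    n
        Number of patients.
    p_death
        Probability of death within follow-up.
    p_max
        Probability, among survivors, of the maximum value (never on support).
    interior_mean, interior_dispersion
        Mean and dispersion (``Var = m + m^2/k``) of the untruncated negative
        binomial for survivors' free days, truncated to {1..max_days-1}.
    death_day_geom_p
        Success probability of the geometric death-day distribution
        (truncated to 1..max_days); affects only the daily-state expansion,
        never the outcome value.
    p_covariate, covariate_effect
        Optional single binary prognostic covariate: prevalence, and additive
        shift of the interior mean for covariate-positive patients.
    """

    n: int
    p_death: float
    p_max: float
    interior_mean: float
    interior_dispersion: float
    death_day_geom_p: float = 0.15
    p_covariate: float = 0.0
    covariate_effect: float = 0.0

    def validate(self, spec: OutcomeSpec) -> None:
        for name in ("p_death", "p_max", "death_day_geom_p", "p_covariate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n < 1:
            raise ConfigError("scenario needs n >= 1")
        if not 0.0 < self.death_day_geom_p <= 1.0:
            raise ConfigError("death_day_geom_p must be in (0, 1]")
        means = [self.interior_mean]
        if self.p_covariate > 0:
            means.append(self.interior_mean + self.covariate_effect)
        for m in means:
            if not 0.0 < m < spec.max_days:
                raise ConfigError(f"interior mean {m} outside (0, {spec.max_days})")
        if self.interior_dispersion <= 0:
            raise ConfigError("interior_dispersion must be > 0")


COVID_LIKE = {
    "control": ArmScenario(n=485, p_death=0.32, p_max=0.25,
                           interior_mean=20.0, interior_dispersion=3.0),
    "intervention": ArmScenario(n=486, p_death=0.28, p_max=0.28,
                                interior_mean=21.0, interior_dispersion=3.0),
}


def _arm_rng(seed: int, arm: str) -> np.random.Generator:
    # child stream keyed by arm name: inserting an arm leaves others untouched
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(arm.encode())])
    )


def _interior_pmf(mean: float, dispersion: float, max_days: int) -> tuple[np.ndarray, np.ndarray]:
    """pmf of free days: NB(mean, dispersion) truncated to {1..max_days-1}."""
    support = np.arange(1, max_days)
    p = dispersion / (dispersion + mean)
    w = stats.nbinom.pmf(support, dispersion, p)
    total = w.sum()
    if total <= 0:
        raise ConfigError("interior distribution has no mass on 1..max_days-1")
    return support, w / total


def scenario_true_mean(s: ArmScenario, spec: OutcomeSpec) -> float:
    """Closed-form expected outcome value under a scenario.

    Mixture mean ``p_death * death_value + (1 - p_death) *
    [p_max * max_days + (1 - p_max) * E(interior)]`` with the interior
    expectation computed by exact summation over the truncated support.
    Under ``actual`` death handling non-survivors contribute 0 days because
    the generator keeps them on life support until death.
    """
    s.validate(spec)
    death_value = -1.0 if spec.death_handling == "penalize_minus_one" else 0.0

    def e_interior(mean):
        support, pmf = _interior_pmf(mean, s.interior_dispersion, spec.max_days)
        return float(support @ pmf)

    if s.p_covariate > 0:
        ei = ((1 - s.p_covariate) * e_interior(s.interior_mean)
              + s.p_covariate * e_interior(s.interior_mean + s.covariate_effect))
    else:
        ei = e_interior(s.interior_mean)
    surv = s.p_max * spec.max_days + (1 - s.p_max) * ei
    return float(s.p_death * death_value + (1 - s.p_death) * surv)


def scenario_true_var(s: ArmScenario, spec: OutcomeSpec) -> float:
    """Exact outcome variance under a scenario (for SE-based checks)."""
    s.validate(spec)
    death_value = -1.0 if spec.death_handling == "penalize_minus_one" else 0.0
    support, pmf = _interior_pmf(s.interior_mean, s.interior_dispersion, spec.max_days)
    if s.p_covariate > 0:
        s2, p2 = _interior_pmf(s.interior_mean + s.covariate_effect,
                               s.interior_dispersion, spec.max_days)
        values = np.concatenate([[death_value, spec.max_days], support, s2])
        probs = np.concatenate([
            [s.p_death, (1 - s.p_death) * s.p_max],
            (1 - s.p_death) * (1 - s.p_max) * (1 - s.p_covariate) * pmf,
            (1 - s.p_death) * (1 - s.p_max) * s.p_covariate * p2,
        ])
    else:
        values = np.concatenate([[death_value, spec.max_days], support])
        probs = np.concatenate([
            [s.p_death, (1 - s.p_death) * s.p_max],
            (1 - s.p_death) * (1 - s.p_max) * pmf,
        ])
    mean = values @ probs
    return float((values - mean) ** 2 @ probs)


def _simulate_arm(arm: str, s: ArmScenario, spec: OutcomeSpec, seed: int):
    rng = _arm_rng(seed, arm)
    died = rng.random(s.n) < s.p_death
    covariate = (rng.random(s.n) < s.p_covariate) if s.p_covariate > 0 else np.zeros(s.n, bool)
    at_max = ~died & (rng.random(s.n) < s.p_max)
    raw = np.zeros(s.n, dtype=int)
    raw[at_max] = spec.max_days
    interior = ~died & ~at_max
    for cov_val in (False, True):
        sel = interior & (covariate == cov_val)
        if not sel.any():
            continue
        mean = s.interior_mean + (s.covariate_effect if cov_val else 0.0)
        support, pmf = _interior_pmf(mean, s.interior_dispersion, spec.max_days)
        raw[sel] = rng.choice(support, size=int(sel.sum()), p=pmf)
    # death day for the daily expansion: geometric truncated to 1..max_days
    death_day = np.zeros(s.n, dtype=int)
    if died.any():
        d = np.arange(1, spec.max_days + 1)
        w = stats.geom.pmf(d, s.death_day_geom_p)
        death_day[died] = rng.choice(d, size=int(died.sum()), p=w / w.sum())
    return raw, died, at_max, covariate, death_day


def simulate_trial(
    scenarios: dict[str, ArmScenario],
    spec: OutcomeSpec,
    seed: int,
    expand_daily: bool = False,
):
    """Simulate a multi-arm trial; deterministic given ``seed``.

    Returns a per-patient trial table (and, when ``expand_daily``, a matching
    daily-state table whose collapse through
    :func:`dawols.outcome.build_outcome_from_daily` reproduces the outcomes
    exactly). Patient ids are ``{arm}-{i:05d}``; the first scenario key is the
    control arm.
    """
    if len(scenarios) < 2:
        raise ConfigError("need at least 2 arms")
    parts = []
    daily_rows = []
    arm_order = list(scenarios)
    any_cov = any(s.p_covariate > 0 for s in scenarios.values())
    for arm in arm_order:
        s = scenarios[arm]
        s.validate(spec)
        raw, died, at_max, covariate, death_day = _simulate_arm(arm, s, spec, seed)
        if spec.death_handling == "penalize_zero":
            outcome = np.where(died, 0, raw)
        elif spec.death_handling == "penalize_minus_one":
            outcome = np.where(died, -1, raw)
        else:
            outcome = raw
        pids = np.char.add(f"{arm}-", np.char.zfill(np.arange(s.n).astype(str), 5))
        part = pd.DataFrame({
            "patient_id": pids, "arm": arm, "outcome": outcome.astype(int),
            "died": died, "raw_count": raw,
        })
        if any_cov:
            part["covariate"] = covariate.astype(int)
        parts.append(part)
        if expand_daily:
            for i in range(s.n):
                daily_rows.extend(
                    _expand_patient(str(pids[i]), int(raw[i]), bool(died[i]),
                                    int(death_day[i]), spec.max_days)
                )
    trial = pd.concat(parts, ignore_index=True)
    trial["arm"] = pd.Categorical(trial["arm"], categories=arm_order, ordered=True)
    trial = validate_trial_table(trial, spec)
    if expand_daily:
        return trial, pd.DataFrame(daily_rows, columns=["patient_id", "day", "state"])
    return trial


def _expand_patient(pid: str, free_days: int, died: bool, death_day: int, max_days: int):
    """One patient's daily trajectory, consistent with (free_days, died).

    Non-survivors stay on life support until the death day (0 free days).
    Survivors carry a single leading life-support block of ``max_days -
    free_days`` days, then up to 2 hospital days, then home.
    """
    states = []
    if died:
        states = ["life_support"] * (death_day - 1) + ["dead"] * (max_days - death_day + 1)
    else:
        support = max_days - free_days
        hosp = min(2, free_days)
        states = ["life_support"] * support + ["hospital"] * hosp + ["home"] * (max_days - support - hosp)
    return [{"patient_id": pid, "day": d + 1, "state": st} for d, st in enumerate(states)]


# ---------------------------------------------------------------------------
# proportional-odds-consistent ordinal data


def simulate_proportional_odds(
    control_probs,
    value_map,
    log_or: float | dict[str, float],
    n_per_arm: int | dict[str, int],
    seed: int,
    arm_names: tuple[str, ...] = ("control", "intervention"),
) -> pd.DataFrame:
    """Simulate ordinal outcomes that satisfy the proportional-odds assumption.

    Control category probabilities are given directly; each non-control arm
    shifts every cumulative logit by its (single) log cumulative odds ratio,
    with positive values meaning better (higher) categories.
    """
    control_probs = np.asarray(control_probs, dtype=float)
    if control_probs.ndim != 1 or len(control_probs) != len(value_map):
        raise ConfigError("control_probs must match value_map length")
    if not np.isclose(control_probs.sum(), 1.0):
        raise ConfigError("control_probs must sum to 1")
    if len(value_map) < 3:
        raise ConfigError("need at least 3 categories")
    cum = np.cumsum(control_probs)[:-1]
    theta = logit(np.clip(cum, 1e-12, 1 - 1e-12))
    rows = []
    value_map = [int(v) for v in value_map]
    for arm in arm_names:
        beta = 0.0 if arm == arm_names[0] else (
            log_or[arm] if isinstance(log_or, dict) else float(log_or)
        )
        n = n_per_arm[arm] if isinstance(n_per_arm, dict) else int(n_per_arm)
        cdf = np.append(expit(theta - beta), 1.0)
        probs = np.diff(np.concatenate([[0.0], cdf]))
        rng = _arm_rng(seed, arm)
        vals = rng.choice(value_map, size=n, p=probs)
        for i, v in enumerate(vals):
            rows.append({"patient_id": f"{arm}-{i:05d}", "arm": arm,
                         "outcome": int(v), "died": bool(v == min(value_map))})
    trial = pd.DataFrame(rows)
    trial["arm"] = pd.Categorical(trial["arm"], categories=list(arm_names), ordered=True)
    return trial


def scenarios_from_file(path) -> tuple[dict[str, ArmScenario], OutcomeSpec]:
    """Read scenario YAML: top-level ``spec`` mapping plus ``arms`` mapping."""
    cfg = yaml.safe_load(open(path))
    spec = OutcomeSpec.from_dict(cfg.get("spec", {}))
    arms = {name: ArmScenario(**kw) for name, kw in cfg["arms"].items()}
    return arms, spec
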