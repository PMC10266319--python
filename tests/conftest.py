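import numpy as np
import pandas as pd
import pytest

import dawols as dw


def recode_for_family(trial: pd.DataFrame, spec: dw.OutcomeSpec, family: str) -> pd.DataFrame:
    """Outcome column on the scale each family models (deaths coded 0 in the
    source table): days for linear/hurdle, proportion for zoib, -1 death code
    for cumlogit."""
    df = trial.copy()
    if family == "zoib":
        df["outcome"] = [
            dw.to_proportion(max(int(v), 0), spec.max_days) for v in df["outcome"]
        ]
    elif family == "cumlogit":
        df.loc[df["died"].to_numpy(), "outcome"] = -1
    return df


@pytest.fixture(scope="session")
def spec_days():
    return dw.OutcomeSpec(28, "penalize_zero", "days")


@pytest.fixture(scope="session")
def covid_trial(spec_days):
    """Two-arm synthetic trial under the package's standard study conditions."""
    return dw.simulate_trial(dw.COVID_LIKE, spec_days, seed=7)


@pytest.fixture(scope="session")
def covid_daily(spec_days):
    scaled = {
        arm: dw.ArmScenario(n=400, p_death=s.p_death, p_max=s.p_max,
                            interior_mean=s.interior_mean,
                            interior_dispersion=s.interior_dispersion)
        for arm, s in dw.COVID_LIKE.items()
    }
    return dw.simulate_trial(scaled, spec_days, seed=11, expand_daily=True)


@pytest.fixture(scope="session")
def fitted(covid_trial, spec_days):
    """All four families fitted to the standard trial with a small draws
    matrix (kept session-scoped so fits are shared across test modules)."""
    fits, datasets = {}, {}
    for family in dw.models.FAMILIES:
        df = recode_for_family(covid_trial, spec_days, family)
        fits[family] = dw.fit_model(family, df, draws=80, seed=5)
        datasets[family] = df
    return fits, datasets
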