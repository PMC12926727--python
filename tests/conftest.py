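"""Shared fixtures: generated cohorts and (expensive, session-scoped) fits."""

import numpy as np
import pytest

from bivgrowth import cohort_data as cd
from bivgrowth import hlm_core as hc
from bivgrowth import synthetic_cohort as sc


@pytest.fixture(scope="session")
def tiny():
    cohort, labels = sc.make_fixture("tiny")
    return {"cohort": cohort, "labels": labels,
            "groups": cd.assign_groups(cohort)}


@pytest.fixture(scope="session")
def small():
    cohort, labels = sc.make_fixture("small")
    groups = cd.assign_groups(cohort)
    return {
        "cohort": cohort, "labels": labels, "groups": groups,
        "frame1": cd.to_model_frame(cohort, (2, 5), 2.0, groups=groups),
        "frame2": cd.to_model_frame(cohort, (6, 11), 6.0, groups=groups),
    }


@pytest.fixture(scope="session")
def medium_bundle():
    """Medium cohort with both age-window models fitted (shared: fitting
    dominates the suite's runtime)."""
    cohort, labels = sc.make_fixture("medium")
    groups = cd.assign_groups(cohort)
    fits, frames, diags = {}, {}, {}
    for model, window, center in (("model1", (2, 5), 2.0),
                                  ("model2", (6, 11), 6.0)):
        frames[model] = cd.to_model_frame(cohort, window, center, groups=groups)
        fits[model], diags[model] = hc.fit(
            frames[model],
            hc.HLMSpec(age_window=window, centering_age=center),
            hc.SamplerConfig(chains=2, warmup=400, draws=500, seed=11, thin=2),
        )
    plugins = {m: hc.plugin_estimates(fits[m]) for m in fits}
    return {
        "cohort": cohort, "labels": labels, "groups": groups,
        "frames": frames, "fits": fits, "diags": diags, "plugins": plugins,
        "config": sc.fixture_config("medium"),
        "target": [g for g in groups if g.in_target],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
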