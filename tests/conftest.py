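"""Shared fixtures: synthetic ground truth and counterfactual scenario runs."""

import pandas as pd
import pytest

from amews import scenarios, synth
from amews.stressors import effectiveness_factors


@pytest.fixture(scope="session")
def default_truth():
    """Default-condition ground truth: 5 wards x 24 months, 30 households/site."""
    cfg = synth.GeneratorConfig(seed=1234)
    return synth.generate_ground_truth(cfg)


@pytest.fixture(scope="session")
def scenario_means():
    """Per-replicate overall mean prevalence for every shock x adaptation cell.

    20 paired replicates per scenario on the default fixture, sharing the
    seed stream so cross-scenario contrasts are paired.
    """
    cfg = synth.GeneratorConfig(seed=42)
    hh = synth.generate_households(cfg)
    fac = effectiveness_factors(synth.generate_stressors(cfg))
    params = synth.default_true_params(seed=42)
    specs = [
        scenarios.build_scenario("baseline"),
        scenarios.build_scenario("climate"),
        scenarios.build_scenario("economic"),
        scenarios.build_scenario("combined"),
        scenarios.build_scenario("climate", "constrained"),
        scenarios.build_scenario("climate", "enabled"),
        scenarios.build_scenario("economic", "constrained"),
        scenarios.build_scenario("economic", "enabled"),
    ]
    traj, _ = scenarios.run_counterfactuals(params, hh, fac, specs, replicates=20, seed=42)
    return traj.groupby(["scenario", "replicate"])["prevalence_pct"].mean().unstack(0)


@pytest.fixture(scope="session")
def benign_truth():
    """Fully capable single-child households, no shocks: the zero-prevalence limit."""
    cfg = synth.GeneratorConfig(seed=42, benign=True)
    return synth.generate_ground_truth(cfg)
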