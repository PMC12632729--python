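import numpy as np
import pandas as pd
import pytest

from heatsurge.basis import CrossBasisSpec, build_crossbasis
from heatsurge.models import adjust_counts, build_design, fit_quasipoisson
from heatsurge.synthetic import SimConfig, default_truth, gen_panel

# one fixed seed shared by all stochastic checks
STOCHASTIC_SEED = 7


@pytest.fixture(scope="session")
def monotone_truth():
    """Monotone-increasing truth peaking at relative risk 1.10."""
    return default_truth()


@pytest.fixture(scope="session")
def recovery_fits(monotone_truth):
    """Five fitted synthetic counties (3 years, base rate 50)."""
    cfg = SimConfig(n_counties=5, n_years=3, base_rate=50.0, seed=STOCHASTIC_SEED)
    out = []
    for i in range(cfg.n_counties):
        panel = adjust_counts(gen_panel(cfg, i, monotone_truth))
        spec = CrossBasisSpec.from_temperatures(panel.tmax)
        cb = build_crossbasis(panel.tmax, spec)
        design = build_design(panel, cb)
        out.append((panel, spec, cb, design, fit_quasipoisson(design)))
    return out


@pytest.fixture(scope="session")
def fitted_county(recovery_fits):
    return recovery_fits[0]


@pytest.fixture(scope="session")
def strong_fit():
    """High-signal fit (peak RR 1.5, Poisson noise, base rate 200) whose
    cumulative curve is cleanly increasing — used for scenario monotonicity."""
    cfg = SimConfig(n_years=3, base_rate=200.0, dispersion=1.0, seed=STOCHASTIC_SEED)
    truth = default_truth(max_log_rr=np.log(1.5))
    panel = adjust_counts(gen_panel(cfg, 0, truth))
    spec = CrossBasisSpec.from_temperatures(panel.tmax, future=panel.tmax + 3.0)
    cb = build_crossbasis(panel.tmax, spec)
    design = build_design(panel, cb)
    return panel, spec, cb, design, fit_quasipoisson(design)


@pytest.fixture(scope="session")
def demo_inputs(tmp_path_factory):
    """Synthetic panels + warming scenarios + region map on disk."""
    from heatsurge.synthetic import (
        gen_panels,
        gen_scenario_deltas,
        write_panels,
        write_region_map,
        write_scenarios,
    )

    d = tmp_path_factory.mktemp("demo")
    cfg = SimConfig(n_counties=5, n_years=3, seed=STOCHASTIC_SEED)
    panels = gen_panels(cfg, default_truth())
    write_panels(panels, d / "panels.csv")
    write_region_map(panels, d / "region_map.csv")
    write_scenarios(gen_scenario_deltas(3, seed=STOCHASTIC_SEED), d / "scenarios.csv")
    return d
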