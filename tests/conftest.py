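import numpy as np
import pytest

import bucketrt as b
from bucketrt.speciation import EquilibriumSystem


@pytest.fixture(scope="session")
def carbon_network():
    return b.synthetic.load_example_network("carbon_network.toml", "carbon.dbs")


@pytest.fixture(scope="session")
def nitrogen_network():
    return b.synthetic.load_example_network("nitrogen_network.toml", "nitrogen.dbs")


@pytest.fixture(scope="session")
def carbon_sz_system(carbon_network):
    """Shallow-zone equilibrium system of the carbon example (includes the
    sorption reaction), with a soil-typical CO2 partial pressure."""
    return EquilibriumSystem.from_network(
        carbon_network, "SZ", fixed_activities={"CO2(g)": 10.0 ** -2.0}
    )


@pytest.fixture(scope="session")
def carbon_totals():
    """A feasible set of component totals (total inorganic carbon ~1e-3,
    near-neutral pH) for speciation tests."""
    return {"DOC": 2e-4, "HCO3-": 8e-4, "Ca++": 2e-5, "H+": 2e-4, ">X": 1e-3}


@pytest.fixture(scope="session")
def w9_forcing_10y():
    from dataclasses import replace

    return b.generate_forcing(3650, replace(b.W9_PRESET, seed=20240101))


@pytest.fixture(scope="session")
def carbon_run():
    """One shared 2-year carbon simulation (plus spin-up)."""
    return b.run_simulation(b.carbon_example_config(years=2, seed=42))


@pytest.fixture(scope="session")
def nitrogen_runs():
    """Nitrate simulations with and without the deep denitrification sink."""
    with_dz = b.run_simulation(
        b.nitrogen_example_config(years=2, seed=42, denitrification_dz=True))
    without_dz = b.run_simulation(
        b.nitrogen_example_config(years=2, seed=42, denitrification_dz=False))
    return with_dz, without_dz


@pytest.fixture(scope="session")
def tracer_run_zero_pet():
    """Conservative tracer under steady chemistry and no evapotranspiration:
    the classic well-mixed-reactor limit where every store relaxes to the
    input concentration."""
    cfg = b.tracer_example_config(years=3, seed=5)
    from dataclasses import replace

    spec = replace(cfg.forcing_spec, seed=5, pet_coeff=0.0)
    forcing = b.generate_forcing(3 * 365, spec)
    cfg.forcing = forcing
    cfg.spinup_years = 0
    return cfg, b.run_simulation(cfg)
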