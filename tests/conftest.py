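import numpy as np
import pandas as pd
import pytest

from inhibkin import (
    GeneralParams,
    MechanismClass,
    RateDataset,
    TraditionalParams,
    reference_design,
    simulate_dataset,
)

# Regimes matching the published mechanism tables: enzyme/inhibitor pairs
# expressed as general-model parameters (Ks, Vmax are scale-free choices).
WT_IMIDAZOLE = GeneralParams(Ks=1.3, Vmax=1.0, Ki=45.0, gamma=0.5, beta=1.0)
WT_TRIS = GeneralParams(Ks=1.3, Vmax=1.0, Ki=36.0, gamma=0.5, beta=0.0)
F251A_IMIDAZOLE = GeneralParams(Ks=1.3, Vmax=1.0, Ki=36.0, gamma=0.5, beta=0.6)
F251A_TRIS = GeneralParams(Ks=1.3, Vmax=1.0, Ki=120.0, gamma=1.0 / 11.0, beta=0.0)


@pytest.fixture(scope="session")
def wt_imidazole_data() -> RateDataset:
    """Noiseless partial-competitive rates under the reference design."""
    return simulate_dataset(WT_IMIDAZOLE, reference_design())


@pytest.fixture(scope="session")
def wt_tris_data() -> RateDataset:
    """Noiseless linear-mixed rates under the reference design."""
    return simulate_dataset(WT_TRIS, reference_design())


@pytest.fixture(scope="session")
def f251a_imidazole_data() -> RateDataset:
    """Noiseless partial-mixed (beta = 0.6) rates."""
    return simulate_dataset(F251A_IMIDAZOLE, reference_design())


@pytest.fixture()
def uncompetitive_data() -> RateDataset:
    """Rates with parallel double-reciprocal lines (uncompetitive phenotype).

    1/v = (Ks/Vmax)(1/S) + (1/Vmax)(1 + I/Ki): constant slope, rising
    intercept.  Built directly since this mechanism lies outside the
    intersecting family the package models.
    """
    design = reference_design()
    rows = []
    Ks, Vmax, Ki = 1.3, 1.0, 30.0
    for S in design.S_values:
        for I in design.I_values:
            v = 1.0 / ((Ks / Vmax) / S + (1.0 + I / Ki) / Vmax)
            for rep in range(3):
                rows.append({"S_mM": S, "I_mM": I, "replicate": rep, "v0": v})
    return RateDataset(data=pd.DataFrame(rows))


def make_traditional(mechanism: MechanismClass, **overrides) -> TraditionalParams:
    """Convenience constructor with table-like defaults per mechanism."""
    defaults = {
        MechanismClass.LINEAR_COMPETITIVE: dict(Ki_t=18.0),
        MechanismClass.LINEAR_NONCOMPETITIVE: dict(Ki_t=30.0),
        MechanismClass.LINEAR_MIXED: dict(Ki_t=12.0, alpha=3.0),
        MechanismClass.PARTIAL_COMPETITIVE: dict(Ki_t=15.0, alpha=3.0, beta=1.0),
        MechanismClass.PARTIAL_NONCOMPETITIVE: dict(Ki_t=30.0, beta=0.6),
        MechanismClass.PARTIAL_MIXED: dict(Ki_t=12.0, alpha=3.0, beta=0.6),
    }[mechanism]
    defaults.update(overrides)
    return TraditionalParams(Ks=1.3, Vmax=1.0, mechanism=mechanism, **defaults)
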