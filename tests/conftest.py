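import numpy as np
import pandas as pd
import pytest
from scipy import special

from vialtox.design import AssaySchedule, ScreenDesign, TruthParams

PAPER_DOSES = np.array([0.0, 3.125, 6.25, 12.5, 25.0, 50.0])


def loglogistic_curve(d, g=0.05, bmc50=20.0, b=4.0):
    """Generating dose-response curve (independent of the fitted code path)."""
    d = np.asarray(d, dtype=float)
    er = np.where(d > 0,
                  special.expit(b * (np.log(np.maximum(d, 1e-300))
                                     - np.log(bmc50))), 0.0)
    return g + (1 - g) * er


def binomial_counts(rng, doses, n_per_group, g=0.05, bmc50=20.0, b=4.0):
    p = loglogistic_curve(doses, g, bmc50, b)
    return rng.binomial(n_per_group, p)


@pytest.fixture
def design():
    return ScreenDesign()


@pytest.fixture
def schedule():
    return AssaySchedule()


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


@pytest.fixture
def morphology_df(design):
    from vialtox.synthetic import simulate_morphology

    truth = TruthParams(g=0.05, bmc50_true=20.0, slope_b=4.0, sigma_vial=0.3)
    return simulate_morphology(design, truth, seed=101)


def make_auc_table(rng, concs=(0.0, 3.125, 6.25, 12.5, 25.0, 50.0),
                   n_wells=32, shift_dark=None, shift_light=None,
                   base_light=30.0, base_dark=75.0, sd=3.0,
                   chemical="chem"):
    """Synthetic per-well AUC table with optional per-conc mean shifts."""
    shift_dark = shift_dark or {}
    shift_light = shift_light or {}
    rows = []
    for c in concs:
        al = rng.normal(base_light + shift_light.get(c, 0.0), sd, n_wells)
        ad = rng.normal(base_dark + shift_dark.get(c, 0.0), sd, n_wells)
        for i in range(n_wells):
            rows.append((chemical, c, 1 + i // 96, f"W{c}_{i}", al[i], ad[i]))
    return pd.DataFrame(rows, columns=["chemical", "conc_um", "plate",
                                       "well", "auc_light", "auc_dark"])
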