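import numpy as np
import pandas as pd
import pytest

from toxvar.simulate import (
    SimulationConfig,
    generate_dose_ladder_experiment,
    generate_variation_experiment,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def synthetic_experiment(default_config):
    """One full synthetic experiment at the full design sizes."""
    cages, leaves, truth = generate_variation_experiment(default_config)
    ladder = pd.concat(
        [generate_dose_ladder_experiment(default_config, r)
         for r in ("rgr", "herbivory")], ignore_index=True)
    return cages, leaves, ladder, truth


@pytest.fixture()
def toy_leaves():
    """4 plants x 2 leaves; every plant eats 0.4 of its low-dose leaf and
    0.1 of its high-dose leaf."""
    rows = []
    for i in range(4):
        for level, dose, p in (("low_dose", 1.28, 0.4), ("high_dose", 2.50, 0.1)):
            rows.append({"plant_id": f"p{i}", "cage_id": f"c{i}",
                         "mean_treatment": "high", "leaf_dose_level": level,
                         "dose_nmol_mg": dose, "herbivory_prop": p})
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_cages():
    """Two arms of three cages with known RGR values: constant arm mean 0.10,
    variable arm mean 0.05."""
    rows = []
    for arm, vals in (("constant", [0.10, 0.35, -0.15]),
                      ("intra", [0.05, 0.30, -0.20])):
        for i, v in enumerate(vals):
            rows.append({"cage_id": f"{arm}{i}", "mean_treatment": "high",
                         "variation_treatment": arm, "rgr_per_h": v,
                         "herbivory_prop": 0.2, "pre_weight_mg": 15.0,
                         "n_leaves": 7, "session": 1})
    return pd.DataFrame(rows)
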