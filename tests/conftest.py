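import numpy as np
import pandas as pd
import pytest

from pkherit import PopulationConfig, TruthParams, build_rr_design, simulate_study


@pytest.fixture(scope="session")
def default_population():
    """One default-design synthetic study, shared across tests."""
    return simulate_study(PopulationConfig(), TruthParams(), seed=11)


@pytest.fixture(scope="session")
def small_population():
    """A reduced population (8 sires, 4 batches, 48 pigs) for fast
    end-to-end checks."""
    pop = PopulationConfig(
        n_batches=4,
        sires_per_breed={"Duroc": 2, "Hampshire": 2, "Landrace": 2, "Yorkshire": 2},
        progeny_range=(2, 12), n_animals=48,
    )
    return simulate_study(pop, TruthParams(), seed=7)


def make_toy_conc(n_sires=4, n_progeny=2, hours=(1.0, 4.0, 12.0), seed=0,
                  n_batches=2):
    """Tiny long-format 'concentration' table (generic Gaussian response)
    for likelihood-oracle and design tests."""
    rng = np.random.default_rng(seed)
    rows = []
    breeds = ["Duroc", "Landrace", "Hampshire", "Yorkshire"]
    for s in range(n_sires):
        for p in range(n_progeny):
            aid = f"A{s}{p}"
            for t in hours:
                rows.append({
                    "animal_id": aid, "sire_id": f"S{s}",
                    "breed": breeds[s % len(breeds)],
                    "sex": ["female", "castrated male"][p % 2],
                    "batch": 1 + (s + p) % n_batches,
                    "drug": "FBZ", "compound": "parent",
                    "time_h": t,
                    "conc_ug_per_ml": float(np.exp(rng.normal())),
                })
    return pd.DataFrame(rows)


@pytest.fixture
def toy_conc():
    return make_toy_conc()


@pytest.fixture
def toy_rr_design(toy_conc):
    return build_rr_design(toy_conc, nf=2, nr=1)
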