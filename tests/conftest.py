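import numpy as np
import pandas as pd
import pytest

from osmo.io import CompoundLibrary, CompoundRecord, IonTable


def make_design(
    organisms=("ecoli",),
    levels=("IC0", "IC10", "IC25", "IC50"),
    phases=("polar",),
    n_bio=4,
    n_tech=2,
) -> pd.DataFrame:
    rows = []
    for org in organisms:
        for level in levels:
            for phase in phases:
                for b in range(1, n_bio + 1):
                    for t in range(1, n_tech + 1):
                        rows.append(
                            {
                                "sample_id": f"{org}_{level}_b{b}_t{t}_{phase}",
                                "organism_id": org,
                                "stress_level": level,
                                "extract_phase": phase,
                                "bio_replicate": b,
                                "tech_replicate": t,
                            }
                        )
    return pd.DataFrame(rows)


@pytest.fixture
def glutamate_library() -> CompoundLibrary:
    return CompoundLibrary(
        [
            CompoundRecord(
                compound_id="glu",
                name="glutamate",
                formula={"C": 5, "H": 9, "N": 1, "O": 4},
                logp_ow=-3.69,
                organism_ids=frozenset({"ecoli"}),
                is_osmoprotectant=True,
            )
        ]
    )


@pytest.fixture
def toy_ion_table() -> IonTable:
    design = make_design(n_bio=2, n_tech=1)
    rng = np.random.default_rng(0)
    intensities = pd.DataFrame(
        rng.lognormal(10, 1, size=(3, len(design))), columns=design["sample_id"]
    )
    return IonTable(
        mz=np.array([146.0455, 200.1, 350.2]), intensities=intensities, design=design
    )


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study plus pipeline results, shared across tests."""
    from osmo.pipeline import run_study
    from osmo.simulate import simulate_study

    bundle = simulate_study(seed=42)
    results = run_study(bundle, seed=42)
    return bundle, results
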