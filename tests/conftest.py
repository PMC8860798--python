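import numpy as np
import pandas as pd
import pytest

from twinsem import CohortSpec, TruthRecord, generate_cohort
from twinsem.components import VarianceComponents


@pytest.fixture(scope="session")
def ace_truth():
    """Univariate-style truth: TEs with A/C/E/S = .23/.62/.15/.01, null paths."""
    return TruthRecord(
        components={
            "te": VarianceComponents.from_proportions(0.23, 0.62, 0.15, 0.01),
            "ptsdsx": VarianceComponents(0.2, 0.2, 0.6, 0.0),
        },
        c=0.0,
    )


@pytest.fixture(scope="session")
def mediation_truth():
    """Trivariate truth with one weak mediator and a strong direct path."""
    return TruthRecord.standardized(
        exposure_props=(0.23, 0.62, 0.15, 0.01),
        mediator_props={"wm": (0.57, 0.31, 0.11, 0.004)},
        outcome_props=(0.21, 0.18, 0.22, 0.005),
        a={"wm": 0.014},
        b={"wm": 0.027},
        c=0.918,
    )


@pytest.fixture(scope="session")
def small_cohort(mediation_truth):
    """A modest cohort with items, used across measurement/preprocess tests."""
    spec = CohortSpec(
        n_mz_pairs=250,
        n_dz_pairs=250,
        n_sib_pairs=100,
        n_singletons=800,
        n_sites=8,
        seed=11,
    )
    table, truth = generate_cohort(spec, mediation_truth)
    return spec, table, truth


@pytest.fixture()
def pair_frame():
    """Tiny hand-built two-phenotype frame for FIML unit tests."""
    rng = np.random.default_rng(42)
    rows = []
    fam = 0
    for site in ("S0", "S1", "S2"):
        for rel in ("MZ", "DZ", "SIB", "SINGLETON"):
            for _ in range(3):
                k = 1 if rel == "SINGLETON" else 2
                for _m in range(k):
                    rows.append(
                        {
                            "family_id": f"F{fam:03d}",
                            "site_id": site,
                            "relation": rel,
                            "x": rng.normal(),
                            "y": rng.normal(),
                        }
                    )
                fam += 1
    return pd.DataFrame(rows)
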