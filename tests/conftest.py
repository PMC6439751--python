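import numpy as np
import pandas as pd
import pytest

from adoptherit.synthetic_registry import SimulationConfig, simulate_families


def persons_frame(rows):
    """Build a persons table from compact dicts, filling defaults."""
    defaults = {
        "role": "adoptee",
        "sex": "female",
        "birth_date": "1965-01-01",
        "death_date": None,
        "emigration_date": None,
        "county_of_birth": "C1",
        "education": "middle",
    }
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    for col in ("birth_date", "death_date", "emigration_date"):
        out[col] = pd.to_datetime(out[col])
    return out


@pytest.fixture(scope="session")
def recovery_draws():
    """Large liability draw at known h2 = 0.40, c2 = 0 used by the
    estimator-recovery checks."""
    cfg = SimulationConfig(
        n_adoptees=200_000, h2=0.40, c2=0.0, prevalence=0.02, seed=11
    )
    return cfg, simulate_families(cfg)


def pair_table(draws):
    """Pooled adoptee x single-biological-parent 2x2 counts."""
    ad = np.concatenate([draws.affected["adoptee"]] * 2)
    par = np.concatenate(
        [draws.affected["bio_mother"], draws.affected["bio_father"]]
    )
    return (
        int((ad & par).sum()),
        int((ad & ~par).sum()),
        int((~ad & par).sum()),
        int((~ad & ~par).sum()),
    )
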