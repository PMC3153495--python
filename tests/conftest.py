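import numpy as np
import pandas as pd
import pytest

from stainclass import SimConfig, simulate_cohort, simulate_outcomes


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One seeded default-condition cohort (n=143) with outcomes."""
    cfg = SimConfig(seed=7)
    return simulate_outcomes(simulate_cohort(cfg), cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def toy_cohort(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal cohort frame from per-row dicts.

    Missing stain columns default to intensity 0 / percent 0; tumor
    content defaults to 80.
    """
    base = {f"{m}_{k}": 0 for m in ("l858r", "del19", "total_egfr") for k in ("intensity", "percent")}
    base |= {"panck_intensity": 3, "panck_percent": 90.0, "tumor_content": 80.0}
    out = []
    for i, row in enumerate(rows):
        r = dict(base)
        r["patient_id"] = f"T{i:03d}"
        r.update(row)
        out.append(r)
    return pd.DataFrame(out)
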