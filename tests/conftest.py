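import numpy as np
import pandas as pd
import pytest

from steroidmir.lcl import PairedExprSet
from steroidmir.simulate import CohortConfig, LclConfig, generate_cohort, generate_lcl


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic cohort with planted miRNA effects."""
    cfg = CohortConfig(
        n_subjects=150, n_mirna=50, n_true_mirna=5, true_log_or=0.3,
        effect_sd=0.0, seed=42,
    )
    clinical, counts, truth = generate_cohort(cfg)
    return clinical, counts, truth


@pytest.fixture(scope="session")
def small_paired():
    """A small paired DEX-sham expression set with three planted modules."""
    cfg = LclConfig(
        n_probes=200, n_modules=3, module_size_range=(30, 40), n_pairs=40, seed=7
    )
    return generate_lcl(cfg)


@pytest.fixture()
def toy_paired():
    """A deterministic 6-probe, 5-pair expression set for hand checks."""
    rng = np.random.default_rng(3)
    probes = [f"g{i}" for i in range(6)]
    subjects = [f"s{i}" for i in range(5)]
    cols, meta = [], []
    data = rng.normal(8, 1, size=(6, 10))
    for ci, cond in enumerate(("sham", "DEX")):
        for s in subjects:
            cols.append(f"{s}_{cond}")
            meta.append({"sample_id": f"{s}_{cond}", "subject_id": s, "condition": cond})
    values = pd.DataFrame(data, index=probes, columns=cols)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return PairedExprSet(values=values, samples=samples)
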