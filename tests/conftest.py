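import numpy as np
import pandas as pd
import pytest

from tcellatac.simulate import SimConfig, generate_cohort

#: the one fixed seed used wherever a test needs deterministic randomness
TEST_SEED = 20259


@pytest.fixture(scope="session")
def default_bundle():
    """Default-size synthetic cohort (2000 peaks, 60 samples, no insertions)."""
    return generate_cohort(SimConfig(seed=TEST_SEED))


@pytest.fixture(scope="session")
def small_bundle():
    """Small cohort with insertion events, for atlas/fixture round trips."""
    cfg = SimConfig(
        seed=TEST_SEED, n_peaks=120, n_genes=170,
        lib_size_range=(8000, 12000), rna_lib_size_range=(20000, 30000),
        make_insertions=True,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(TEST_SEED)


def null_score_cohort(rng, n_young=5, n_old=5, lineages=("CD4", "CD8"),
                      subsets=("naive", "CM", "EM"), donor_sd=0.5):
    """Sample table + exchangeable null scores with a donor random intercept."""
    rows = []
    donors = [f"Y{i}" for i in range(n_young)] + [f"O{i}" for i in range(n_old)]
    ages = ["young"] * n_young + ["old"] * n_old
    for d, a in zip(donors, ages):
        for lin in lineages:
            for si, s in enumerate(subsets):
                rows.append({"sample": f"{d}_{lin}_{s}", "donor": d, "lineage": lin,
                             "subset": s, "subset_rank": si, "age_group": a})
    samples = pd.DataFrame(rows).set_index("sample", drop=False)
    eff = dict(zip(donors, rng.normal(0, donor_sd, len(donors))))
    vals = rng.normal(0, 1, len(samples)) + samples["donor"].map(eff).to_numpy()
    return samples, pd.Series(vals, index=samples.index)
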