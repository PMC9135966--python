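import warnings

import numpy as np
import pytest

import citeflow as cf


@pytest.fixture(autouse=True)
def _quiet():
    """ML and selector warnings are noise at tiny fixture sizes."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        warnings.filterwarnings("ignore", module="sklearn")
        yield


@pytest.fixture(scope="session")
def small_cohort() -> cf.SimDataset:
    """6-subject two-cohort dataset with planted QC outliers."""
    cfg = cf.SimConfig(n_healthy=4, n_as=2, cells_per_subject=60,
                       qc_outlier_rate=0.01, seed=11)
    return cf.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_de_run():
    """One global-null cohort pushed through QC + VST + the gene DE test."""
    import pandas as pd
    from citeflow.normalize import vst_residuals
    from citeflow.diffexpr import de_genes

    ds = cf.generate_cohort(cf.null_config(seed=5))
    rna, adt, _ = cf.apply_qc(ds.rna, ds.adt, cf.QcThresholds())
    m = vst_residuals(rna)
    cc = pd.DataFrame(m.params["corrected_counts"], index=m.cells,
                      columns=m.features)
    res = de_genes(cc, rna.obs["cohort"].astype(str))
    return res


def nb_sample(rng: np.random.Generator, mu, theta, size=None):
    """Reference Gamma–Poisson draw used by oracle tests."""
    return rng.poisson(rng.gamma(theta, np.asarray(mu) / theta, size=size))
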