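import warnings

import numpy as np
import pytest

from t1qc.iqms import extract_iqms
from t1qc.phantom import PhantomSpec, SiteEffectSpec, generate_phantom, synth_iqm_table

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_phantom():
    """Default 64-cube phantom with magnitude noise, plus its ground truth."""
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Artifact-free, noise-free phantom: intensities are exact
    partial-volume mixtures of the tissue means."""
    return generate_phantom(PhantomSpec(noise_sigma=0.0, seed=2))


@pytest.fixture(scope="session")
def default_extraction(default_phantom):
    """Full 64-metric extraction of the default phantom (reference maps
    from the ground truth)."""
    vol, truth = default_phantom
    return extract_iqms(vol, reference=truth.tissue_maps(), seed=0)


def make_sites(shifts, n=50, prevalences=None, scales=None):
    prevalences = prevalences or [0.35] * len(shifts)
    scales = scales or [1.0] * len(shifts)
    return [
        SiteEffectSpec(
            site_id=f"s{i}",
            n_subjects=n,
            feature_shift=sh,
            feature_scale=sc,
            exclude_prevalence=pv,
        )
        for i, (sh, pv, sc) in enumerate(zip(shifts, prevalences, scales))
    ]


@pytest.fixture()
def batch_effect_table():
    """Four-site table: 3 informative features (1 SD), site shifts and
    site-dependent exclude prevalence — the structure that makes k-fold
    estimates optimistic relative to leave-one-site-out."""
    eff = np.zeros(8)
    eff[:3] = 1.0
    sites = make_sites([0, 3, -3, 6], n=50,
                       prevalences=[0.15, 0.55, 0.30, 0.60])
    return synth_iqm_table(sites, 8, eff, seed=100)
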