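import numpy as np
import pytest

from gestaflux import synthdata as sd


@pytest.fixture(scope="session")
def noiseless_study():
    """Small study with no biological noise, assay offsets on, assay noise off."""
    templates = sd.generate_trajectory_params(seed=11)
    for t in templates:
        t.subject_sd = 0.0
        t.residual_sd = 0.0
    parts, samples = sd.generate_cohort(60, seed=11)
    truth = sd.simulate_concentrations(parts, samples, templates, seed=11)
    assay = sd.default_assay_config(seed=11, theta=(0.0, 0.0))
    fi, bridge, std = sd.simulate_assay_fi(truth, assay, seed=11)
    return {"participants": parts, "samples": samples, "truth": truth,
            "fi_long": fi, "bridge_manifest": bridge, "standards": std,
            "assay": assay, "templates": templates}


@pytest.fixture(scope="session")
def noisy_study():
    """Realistic small study (default noise and artifacts), n=120 women."""
    return sd.generate_study(120, seed=7)


@pytest.fixture(scope="session")
def noisy_panel(noisy_study):
    from gestaflux import assayproc as ap

    panel, curves, reports = ap.build_panel(
        noisy_study["fi_long"], noisy_study["bridge_manifest"],
        noisy_study["standards"], noisy_study["samples"],
        noisy_study["participants"], reference_lot="L1",
    )
    return panel, curves, reports


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
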