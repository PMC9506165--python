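"""Shared fixtures: one synthetic world, imputed and calibrated once."""

import pytest

import saltcvd as sc


@pytest.fixture(scope="session")
def bundle() -> sc.SyntheticBundle:
    """Default noiseless synthetic input bundle."""
    return sc.generate_bundle(sc.SynthConfig(seed=0))


@pytest.fixture(scope="session")
def surface(bundle) -> sc.SaltExposureSurface:
    """Salt surface reconstructed from the synthetic survey tables."""
    return sc.impute_salt(bundle.salt_overall, bundle.salt_by_group)


@pytest.fixture(scope="session")
def calibrated(bundle) -> sc.CalibrationResult:
    return sc.calibrate(bundle.demography.observed_mortality, bundle.m1950)


@pytest.fixture(scope="session")
def params(bundle, calibrated) -> sc.APCParams:
    return sc.APCParams(
        m1950=bundle.m1950,
        p=calibrated.p,
        c=calibrated.c,
        cvd_proportion=bundle.cvd_proportion,
    ).validate()


@pytest.fixture(scope="session")
def scenario_results(bundle, params, surface):
    """Base + four counterfactual runs on the default configuration."""
    return sc.run_all_scenarios(bundle.demography, params, surface)
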