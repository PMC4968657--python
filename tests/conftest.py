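import pytest

import nanofret as nf


@pytest.fixture(scope="session")
def calib():
    """Published exponential calibration of the Cy5.5/Cy7.5 imaging setup."""
    return nf.DEFAULT_CALIBRATION


def _replicate_manifests(name, tmpdir, n=3, seed=1, noise=None):
    scenarios = nf.builtin_scenarios(seed=seed, noise=noise)
    return [
        nf.generate_timeseries(nf.replicate(scenarios[name], i), tmpdir / f"{name}{i}")
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def healthy_manifests(tmp_path_factory):
    """Three noisy healthy-phantom replicates (seeds 1-3)."""
    return _replicate_manifests("healthy", tmp_path_factory.mktemp("healthy"))


@pytest.fixture(scope="session")
def tumor_manifests(tmp_path_factory):
    return _replicate_manifests("tumor_bearing", tmp_path_factory.mktemp("tumor"))


@pytest.fixture(scope="session")
def donor_only_manifests(tmp_path_factory):
    return _replicate_manifests("donor_only", tmp_path_factory.mktemp("donor"))


@pytest.fixture(scope="session")
def noiseless_healthy_manifest(tmp_path_factory):
    scenarios = nf.builtin_scenarios(seed=7, noise=nf.NoiseModel.off())
    return nf.generate_timeseries(
        scenarios["healthy"], tmp_path_factory.mktemp("noiseless") / "healthy"
    )
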