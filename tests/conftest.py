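import pytest

from haplodfe.demography import (DemographicModel, LocusParams, SampleConfig,
                                 SelectionParams)
from haplodfe.ibs import WindowScheme
from haplodfe import trajectories as tj


@pytest.fixture(scope="session")
def small_model():
    """Tiny constant-size scenario shared by the cheaper simulation tests."""
    return dict(
        demography=DemographicModel.constant(300, label="constant-N300"),
        sample=SampleConfig(S=400, f=0.01, n=4),
        locus=LocusParams(u=1.5e-6, r=3e-7, length=50_000, focal_pos=0.0),
        scheme=WindowScheme.equidistant(6, 20_000.0),
    )


@pytest.fixture(scope="session")
def neutral_trajectories(small_model):
    return tj.sample_conditioned_trajectories(
        small_model["demography"], SelectionParams(0.0), 60.0,
        small_model["sample"], 60, seed=11)


@pytest.fixture(scope="session")
def one_trajectory(neutral_trajectories):
    # a moderately old trajectory, informative for T2-based checks
    return max(neutral_trajectories, key=lambda t: t.age)
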