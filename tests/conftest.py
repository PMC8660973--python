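import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synmorph.annotations import Point2D, Polyline, SectionAnnotation, VesicleAnnotation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_section(
    centers,
    diameters=None,
    az=((0.0, 0.0), (1000.0, 0.0)),
    trace=((-1600.0, 0.0), (2600.0, 0.0)),
    cisternae=(),
    kinds=None,
    stages=None,
    synapse_id="s1",
    treatment="untreated",
    distance=None,
    thickness=70.0,
):
    """Hand-built section: vesicle centers in nm over a 1 um active zone on
    a flat membrane trace (unless overridden)."""
    centers = list(centers)
    if diameters is None:
        diameters = [50.0] * len(centers)
    if kinds is None:
        kinds = ["uncoated"] * len(centers)
    if stages is None:
        stages = [None] * len(centers)
    vesicles = [
        VesicleAnnotation(
            id=f"v{i}", center=Point2D(float(x), float(y)), diameter=float(d), kind=k, stage=st
        )
        for i, ((x, y), d, k, st) in enumerate(zip(centers, diameters, kinds, stages))
    ]
    return SectionAnnotation(
        synapse_id=synapse_id,
        axon_id="a1",
        treatment=treatment,
        distance_from_injection=distance,
        section_thickness=thickness,
        vesicles=vesicles,
        active_zone=Polyline(az, closed=False),
        membrane_trace=Polyline(trace, closed=False),
        cisternae=[Polyline(c, closed=True) for c in cisternae],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_experiment():
    from synmorph.simulate import SyntheticParams, generate_experiment

    params = SyntheticParams(n_synapses_per_zone=4, base_sv_count_mean=40.0)
    return generate_experiment(params, seed=11)
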