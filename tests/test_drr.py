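import numpy as np
import pytest

from polarscope.decomposition import mueller_diattenuator, mueller_linear_retarder
from polarscope.drr import (
    drr_intensity,
    reconstruct_mueller,
    simulate_measurement,
    trace_harmonics,
    trace_to_dataframe,
)
from polarscope.stokes import mueller_of_polarizer, mueller_of_waveplate

SAMPLES = {
    "air": np.eye(4),
    "pol_0": mueller_of_polarizer(0.0),
    "pol_45": mueller_of_polarizer(45.0),
    "qwp_30": mueller_of_waveplate(np.pi / 2, 30.0),
}


@pytest.mark.parametrize("name", sorted(SAMPLES))
@pytest.mark.parametrize("method", ["lstsq", "fourier"])
def test_round_trip_ideal_samples(name, method):
    M = SAMPLES[name]
    trace = simulate_measurement(M)
    M_hat = reconstruct_mueller(trace, method=method)
    assert np.allclose(M_hat, M, atol=1e-12)


def test_methods_agree_on_random_matrix(rng):
    M = mueller_linear_retarder(0.8, 10.0) @ mueller_diattenuator(0.3, 25.0)
    trace = simulate_measurement(M)
    a = reconstruct_mueller(trace, method="lstsq")
    b = reconstruct_mueller(trace, method="fourier")
    assert np.allclose(a, b, atol=1e-12)


def test_intensities_nonnegative_for_physical_sample():
    trace = simulate_measurement(mueller_of_polarizer(17.0))
    assert np.all(trace.intensities >= -1e-15)


def test_air_intensity_at_zero_steps():
    # PSG at 0 deg emits horizontal light; PSA at 0 deg passes it fully
    assert drr_intensity(np.eye(4), 0.0) == pytest.approx(0.5)


def test_too_few_steps_rejected():
    with pytest.raises(ValueError):
        simulate_measurement(np.eye(4), n_steps=10)


def test_harmonics_require_enough_steps():
    trace = simulate_measurement(np.eye(4), n_steps=20)
    with pytest.raises(ValueError):
        trace_harmonics(trace)


def test_unknown_method_rejected():
    trace = simulate_measurement(np.eye(4))
    with pytest.raises(ValueError):
        reconstruct_mueller(trace, method="magic")


def test_trace_dataframe_shape():
    df = trace_to_dataframe(simulate_measurement(np.eye(4)))
    assert len(df) == 30
    assert {"theta_deg", "intensity"} <= set(df.columns)
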