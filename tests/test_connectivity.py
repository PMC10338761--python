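"""Phase extraction and PLI: analytic examples, oracle equivalence,
volume-conduction rejection and matrix invariants."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fcreeg as fc
from fcreeg.connectivity import (connectivity_matrix, instantaneous_phase,
                                 pli, pli_matrix, wrap_phase)
from fcreeg.montage import CANONICAL_CHANNELS


def _naive_pli(phi1, phi2):
    """Literal loop evaluation of the PLI definition (test oracle)."""
    total = 0.0
    for a, b in zip(phi1, phi2):
        d = a - b
        while d <= -math.pi:
            d += 2 * math.pi
        while d > math.pi:
            d -= 2 * math.pi
        if abs(d) > 1e-9:
            total += math.copysign(1.0, d)
    return abs(total / len(phi1))


def test_phase_of_cosine_starts_near_zero():
    t = np.arange(1280) / 128.0
    phi = instantaneous_phase(np.cos(2 * np.pi * 10 * t))
    assert abs(phi[0]) < 1e-2


def test_quarter_cycle_lag_recovered_in_phase_difference():
    t = np.arange(1280) / 128.0
    p1 = instantaneous_phase(np.sin(2 * np.pi * 10 * t))
    p2 = instantaneous_phase(np.sin(2 * np.pi * 10 * t - np.pi / 2))
    d = wrap_phase(p1 - p2)[256:1024]  # central samples, no edge effects
    np.testing.assert_allclose(d, np.pi / 2, atol=1e-3)


def test_constant_signal_rejected():
    with pytest.raises(ValueError, match="constant"):
        instantaneous_phase(np.zeros(100))
    with pytest.raises(ValueError, match="constant"):
        instantaneous_phase(np.full(100, 3.3))


def test_pli_analytic_values():
    T = 1000
    assert pli(np.full(T, 0.7), np.full(T, 0.7 - np.pi / 2)) == 1.0
    phi = np.linspace(-3, 3, T)
    assert pli(phi, phi) == 0.0
    # 75% positive, 25% negative wrapped differences -> |0.75 - 0.25| = 0.5
    d = np.array([0.5] * 750 + [-0.5] * 250)
    assert pli(d, np.zeros(1000)) == pytest.approx(0.5, abs=1e-12)


def test_pli_symmetry_and_length_check(rng):
    a, b = rng.uniform(-np.pi, np.pi, (2, 500))
    assert pli(a, b) == pli(b, a)
    with pytest.raises(ValueError):
        pli(a, b[:-1])


def test_vectorized_matrix_matches_naive_oracle(rng):
    phases = rng.uniform(-np.pi, np.pi, (16, 200))
    m = pli_matrix(phases)
    for i in range(16):
        for j in range(i + 1, 16):
            assert m[i, j] == pytest.approx(
                _naive_pli(phases[i], phases[j]), abs=1e-12)
    np.testing.assert_array_equal(m, m.T)
    np.testing.assert_array_equal(np.diag(m), 0.0)


def test_zero_lag_scaled_mixture_gives_zero(rng):
    """Volume-conduction emulation: y = alpha*x has no consistent lag."""
    t = np.arange(1280) / 128.0
    x = np.sin(2 * np.pi * 11 * t) + 0.2 * rng.standard_normal(1280)
    for alpha in (0.5, 1.0, 3.7):
        assert pli(instantaneous_phase(x), instantaneous_phase(alpha * x)) == 0.0


@settings(deadline=None, max_examples=20, derandomize=True)
@given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 10_000))
def test_amplitude_scale_invariance(scale, seed):
    """Phases, hence PLI, ignore positive amplitude scaling."""
    rng = np.random.default_rng(seed)
    t = np.arange(640) / 128.0
    x = np.sin(2 * np.pi * 9 * t) + 0.3 * rng.standard_normal(640)
    y = np.sin(2 * np.pi * 9 * t + 0.8) + 0.3 * rng.standard_normal(640)
    base = pli(instantaneous_phase(x), instantaneous_phase(y))
    scaled = pli(instantaneous_phase(scale * x), instantaneous_phase(y))
    assert scaled == pytest.approx(base, abs=1e-12)


def test_independent_phases_pli_vanishes_with_length(rng):
    """For uniform random phases at T = 1280, mean PLI over 100 runs < 0.05."""
    vals = [pli(rng.uniform(-np.pi, np.pi, 1280),
                rng.uniform(-np.pi, np.pi, 1280)) for _ in range(100)]
    assert np.mean(vals) < 0.05


def _epoch_from(data):
    return fc.Epoch(subject_id="s", group="SZ", index=0, fs=128.0,
                    data=data, band="beta")


def test_connectivity_matrix_structure(beta_matrices):
    m = beta_matrices[0]
    assert m.values.shape == (16, 16)
    np.testing.assert_array_equal(m.values, m.values.T)
    np.testing.assert_array_equal(np.diag(m.values), 0.0)
    assert 0.0 <= m.values.min() and m.values.max() <= 1.0


def test_matrix_entry_matches_pairwise_pli(rng):
    data = rng.standard_normal((16, 1280))
    ep = _epoch_from(data)
    m = connectivity_matrix(ep)
    expected = pli(instantaneous_phase(data[3]), instantaneous_phase(data[7]))
    assert m.values[3, 7] == pytest.approx(expected, abs=1e-12)


def test_identical_channels_give_zero_matrix(rng):
    row = np.sin(2 * np.pi * 10 * np.arange(1280) / 128.0)
    m = connectivity_matrix(_epoch_from(np.tile(row, (16, 1))))
    np.testing.assert_array_equal(m.values, 0.0)


def test_constant_channel_named_in_error(rng):
    data = rng.standard_normal((16, 1280))
    data[9] = 5.0  # Cz in canonical order
    with pytest.raises(ValueError, match="Cz"):
        connectivity_matrix(_epoch_from(data))


def test_matrix_validation_rejects_bad_values():
    bad = np.full((16, 16), 1.5)
    np.fill_diagonal(bad, 0.0)
    with pytest.raises(ValueError):
        fc.ConnectivityMatrix(values=bad, band="beta", subject_id="s",
                              epoch_index=0, group="SZ")
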