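"""CAP signal chain: filtering, averaging, measurement, latency tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nervestretch.signal import (
    CAPTrace,
    CAPPreprocessor,
    cap_reduction,
    compare_latencies,
    extract_and_average,
    measure_cap,
    preprocess,
)

FS = 20_000.0


def make_trace(v, onsets=(0.5,), fs=FS):
    v = np.asarray(v, dtype=float)
    t = np.arange(v.size) / fs
    return CAPTrace(t=t, v=v, fs=fs, stim_onsets=np.asarray(onsets))


def test_line_noise_attenuation():
    """60 Hz sine is suppressed to <5% RMS by the zero-phase 100-5000 Hz band."""
    t = np.arange(int(FS)) / FS
    tr = make_trace(np.sin(2 * np.pi * 60 * t))
    out = preprocess(tr, band=(100.0, 5000.0), median_window=None)
    assert np.sqrt(np.mean(out.v**2)) < 0.05 * np.sqrt(np.mean(tr.v**2))


def test_constant_offset_removed():
    tr = make_trace(np.full(4000, 3.7), onsets=(0.1,))
    out = preprocess(tr)
    assert np.allclose(out.v, 0.0, atol=1e-8)


def test_median_filter_removes_single_sample_spike():
    v = np.zeros(2000)
    v[1000] = 50.0
    tr = make_trace(v, onsets=(0.02,))
    out = preprocess(tr, band=None, median_window=11 / FS)
    neighborhood = np.median(v[995:1006])
    assert out.v[1000] <= neighborhood + 1e-12


def test_baseline_subtraction_idempotent():
    # trace whose pre-stimulus windows are already zero-mean: the baseline
    # stage must change nothing beyond numerical noise
    v = np.zeros(8000)
    t = np.arange(8000) / FS
    v[(t > 0.16) & (t < 0.2)] = np.sin(np.linspace(0, 20, np.sum((t > 0.16) & (t < 0.2))))
    tr = make_trace(v, onsets=(0.15, 0.25))
    once = preprocess(tr, band=None, median_window=None)
    twice = preprocess(once, band=None, median_window=None)
    assert np.max(np.abs(once.v - tr.v)) <= 1e-12
    assert np.max(np.abs(twice.v - once.v)) <= 1e-12


def test_filtering_preserves_length_and_fs():
    tr = make_trace(np.random.default_rng(1).normal(size=5000), onsets=(0.1,))
    out = preprocess(tr)
    assert out.v.size == tr.v.size and out.fs == tr.fs


def test_preprocessor_estimator_wrapper():
    pre = CAPPreprocessor(band=(100.0, 5000.0))
    assert pre.get_params()["band"] == (100.0, 5000.0)
    tr = make_trace(np.ones(4000), onsets=(0.1,))
    out = pre.fit().transform(tr)
    assert np.allclose(out.v, 0.0, atol=1e-8)


def test_band_outside_nyquist_rejected():
    tr = make_trace(np.zeros(1000), onsets=(0.01,))
    with pytest.raises(ValueError):
        preprocess(tr, band=(100.0, 15_000.0))


def test_truncated_baseline_warns():
    tr = make_trace(np.zeros(2000), onsets=(0.0,))
    with pytest.warns(UserWarning, match="truncated"):
        preprocess(tr, band=None, median_window=None)


def test_average_of_identical_epochs():
    epoch = np.sin(np.linspace(0, 4 * np.pi, 200))
    v = np.concatenate([epoch] * 7)
    onsets = np.arange(7) * 200 / FS
    tr = make_trace(v, onsets=onsets)
    t, avg = extract_and_average(tr, epoch_window=200 / FS)
    assert np.allclose(avg, epoch, atol=1e-15)


def test_average_single_epoch():
    epoch = np.linspace(0, 1, 300)
    tr = make_trace(epoch, onsets=(0.0,))
    _, avg = extract_and_average(tr, epoch_window=300 / FS)
    assert np.array_equal(avg, epoch)


def test_average_sqrt_n_noise_law():
    """RMS of the n-epoch average tracks noise_sd / sqrt(n)."""
    rng = np.random.default_rng(42)
    n, m, sd = 100, 400, 1.0
    template = np.exp(-0.5 * ((np.arange(m) - 200) / 30.0) ** 2)
    v = np.tile(template, n) + rng.normal(0, sd, n * m)
    onsets = np.arange(n) * m / FS
    tr = make_trace(v, onsets=onsets)
    _, avg = extract_and_average(tr, epoch_window=m / FS)
    rms_dev = np.sqrt(np.mean((avg - template) ** 2))
    assert rms_dev == pytest.approx(sd / np.sqrt(n), rel=0.3)


def test_average_requires_onsets():
    tr = make_trace(np.zeros(100), onsets=())
    with pytest.raises(ValueError):
        extract_and_average(tr)


def test_measure_cap_noiseless_peak():
    t = np.arange(2000) / FS
    w = 1.0 * np.exp(-0.5 * ((t - 3e-3) / 0.4e-3) ** 2)
    m = measure_cap(t, w, artifact_blank=0.5e-3)
    assert m.amplitude == pytest.approx(1.0, rel=1e-9)
    assert m.latency == pytest.approx(3.0, abs=1e3 / FS)


def test_measure_cap_zero_waveform():
    t = np.arange(2000) / FS
    m = measure_cap(t, np.zeros(2000), artifact_blank=0.5e-3)
    assert m.amplitude == 0.0


def test_measure_cap_ignores_artifact_in_blank_window():
    t = np.arange(2000) / FS
    w = np.zeros(2000)
    w[t < 0.3e-3] = 5.0                      # artifact inside blank window
    w += 1.0 * np.exp(-0.5 * ((t - 3e-3) / 0.4e-3) ** 2)
    m = measure_cap(t, w, artifact_blank=0.5e-3)
    assert m.amplitude == pytest.approx(1.0, rel=1e-6)
    assert m.latency == pytest.approx(3.0, abs=1e3 / FS)


def test_measure_cap_polarity_flag():
    t = np.arange(2000) / FS
    w = -np.exp(-0.5 * ((t - 3e-3) / 0.4e-3) ** 2)
    m = measure_cap(t, w, artifact_blank=0.5e-3, invert=True)
    assert m.amplitude == pytest.approx(1.0, rel=1e-9)


def test_amplitude_estimate_unbiased_over_seeds():
    """Noise-induced bias of the full measurement chain stays within the
    averaging-law bound 2 * sd / sqrt(n_sweeps * samples_in_peak).

    The deterministic filter response is factored out by comparing against
    the noiseless waveform passed through the identical chain.
    """
    n_sweeps, m, sd, amp = 16, 400, 0.05, 1.0
    t_ep = np.arange(m) / FS
    template = amp * np.exp(-0.5 * ((t_ep - 5e-3) / 0.8e-3) ** 2)
    in_peak = int(np.sum(template >= amp / 2))
    onsets = np.arange(n_sweeps) * m / FS

    def chain(v):
        tr = make_trace(v, onsets=onsets)
        clean = preprocess(tr, band=(100.0, 5000.0), median_window=11 / FS)
        _, avg = extract_and_average(clean, epoch_window=m / FS)
        return measure_cap(t_ep, avg, artifact_blank=0.5e-3).amplitude

    ref = chain(np.tile(template, n_sweeps))
    est = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        est.append(chain(np.tile(template, n_sweeps) + rng.normal(0, sd, n_sweeps * m)))
    bias = np.mean(est) - ref
    assert abs(bias) <= 2 * sd / np.sqrt(n_sweeps * in_peak)


@pytest.mark.parametrize(
    "c_ref,c_n,expected",
    [(2.0, 1.0, 50.0), (1.6, 1.6, 0.0), (1.6, 0.4, 75.0)],
)
def test_cap_reduction_values(c_ref, c_n, expected):
    assert cap_reduction(c_ref, c_n) == pytest.approx(expected, abs=1e-12)


@given(c=st.floats(1e-6, 1e3))
def test_cap_reduction_identities(c):
    assert cap_reduction(c, c) == 0.0
    assert cap_reduction(c, 0.0) == 100.0


def test_cap_reduction_negative_passthrough_and_errors():
    assert cap_reduction(1.0, 1.5) == pytest.approx(-50.0)
    with pytest.raises(ValueError):
        cap_reduction(0.0, 1.0)


def test_compare_latencies_identical():
    assert compare_latencies([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)


def test_compare_latencies_frozen():
    t, p = compare_latencies([1.0, 1.1, 0.9], [2.0, 2.1, 1.9])
    assert t == pytest.approx(-12.247448713915883, rel=1e-9)
    assert p == pytest.approx(2.552167494419273e-4, rel=1e-6)


def test_compare_latencies_degenerate():
    assert compare_latencies([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
    with pytest.raises(ValueError):
        compare_latencies([1.0], [2.0, 3.0])
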