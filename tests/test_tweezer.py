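"""Trap-trace analysis: step detection, normalisation, PSD, Lorentzian."""

import numpy as np
import pytest

from heatdyn import (
    TrapTraceModel, TweezerTrace, compute_psd, detect_trapping_step,
    fit_lorentzian, normalize_trace, normalized_rmsd, read_trace,
)
from heatdyn.synthetic import TraceSpec, make_ou_trace


def _fast_spec(**kw):
    """A short, cheap trace spec for unit tests."""
    base = dict(f_c=50.0, stationary_sd=0.005, noise_floor_sd=0.001,
                duration=4.0, sampling_rate=50_000.0, step_time=0.5,
                seed=0)
    base.update(kw)
    return TraceSpec(**base)


# ---------------------------------------------------------------- step


def test_step_detected_near_planted_time():
    trace, spec = make_ou_trace(_fast_spec(seed=3))
    event = detect_trapping_step(trace)
    assert event is not None
    t_step = event.step_index / trace.sampling_rate
    assert abs(t_step - spec.step_time) < 0.1
    assert event.pre_level == pytest.approx(spec.pre_level, rel=1e-3)
    assert event.post_level == pytest.approx(
        spec.pre_level * (1 + spec.step_fraction), rel=1e-2)
    assert event.noise_ratio > 1.1


def test_no_step_returns_none():
    rng = np.random.default_rng(0)
    flat = TweezerTrace(1.0 + rng.normal(0, 0.001, 50_000), 10_000.0)
    assert detect_trapping_step(flat) is None


def test_downward_step_rejected():
    rng = np.random.default_rng(1)
    x = 1.0 + rng.normal(0, 0.001, 40_000)
    x[20_000:] -= 0.3
    x[20_000:] += rng.normal(0, 0.005, 20_000)  # noise DOES increase
    assert detect_trapping_step(TweezerTrace(x, 10_000.0)) is None


def test_mean_jump_without_noise_increase_rejected():
    rng = np.random.default_rng(2)
    x = 1.0 + rng.normal(0, 0.001, 40_000)
    x[20_000:] += 0.3  # clean level shift, same noise
    assert detect_trapping_step(TweezerTrace(x, 10_000.0)) is None


def test_detect_validation():
    trace, _ = make_ou_trace(_fast_spec())
    with pytest.raises(ValueError, match="positive"):
        detect_trapping_step(trace, jump_threshold=0)
    with pytest.raises(ValueError, match="at least 10"):
        detect_trapping_step(trace, window=5)
    tiny = TweezerTrace(np.ones(30), 10.0)
    with pytest.raises(ValueError, match="too short"):
        detect_trapping_step(tiny, window=20)


# ------------------------------------------------- normalisation / nrmsd


def test_normalize_divides_by_pre_level():
    trace, spec = make_ou_trace(_fast_spec(pre_level=2.0, seed=5))
    event = detect_trapping_step(trace)
    norm = normalize_trace(trace, event)
    assert norm.samples.mean() == pytest.approx(1 + spec.step_fraction,
                                                rel=1e-2)
    # margin really removed: fewer samples than raw post-step tail
    assert norm.n_samples < trace.n_samples - event.step_index


def test_normalized_rmsd_analytic():
    x = 1.0 + 0.25 * np.tile([1.0, -1.0], 100)
    tr = TweezerTrace(x, 100.0)
    assert normalized_rmsd(tr) == pytest.approx(0.25)
    shifted = TweezerTrace(x + 0.5, 100.0)
    # 'mean' detrending ignores the offset; 'none' measures from 1.0
    assert normalized_rmsd(shifted) == pytest.approx(0.25)
    assert normalized_rmsd(shifted, detrend="none") == pytest.approx(
        np.sqrt(0.25 ** 2 + 0.5 ** 2))
    with pytest.raises(ValueError, match="detrend"):
        normalized_rmsd(tr, detrend="median")
    with pytest.raises(ValueError, match="100 samples"):
        normalized_rmsd(TweezerTrace(np.ones(50), 100.0))


def test_normalized_rmsd_recovers_ou_sd():
    spec = _fast_spec(seed=11)
    trace, _ = make_ou_trace(spec)
    event = detect_trapping_step(trace)
    norm = normalize_trace(trace, event)
    expected = np.hypot(spec.stationary_sd, spec.noise_floor_sd)
    assert normalized_rmsd(norm) == pytest.approx(expected, rel=0.05)


# ----------------------------------------------------------------- PSD


def test_psd_parseval_white_noise():
    rng = np.random.default_rng(21)
    sigma = 0.3
    tr = TweezerTrace(rng.normal(0, sigma, 2 ** 17), 10_000.0)
    freqs, psd = compute_psd(tr, segment_length=2 ** 12)
    assert np.trapezoid(psd, freqs) == pytest.approx(sigma ** 2, rel=0.05)


def test_psd_sinusoid_peak_location():
    fs, f0 = 10_000.0, 440.0
    t = np.arange(2 ** 16) / fs
    rng = np.random.default_rng(22)
    tr = TweezerTrace(np.sin(2 * np.pi * f0 * t)
                      + rng.normal(0, 0.01, t.size), fs)
    freqs, psd = compute_psd(tr, segment_length=2 ** 13)
    assert abs(freqs[np.argmax(psd)] - f0) <= fs / 2 ** 13


def test_psd_validation():
    tr = TweezerTrace(np.ones(1000), 100.0)
    with pytest.raises(ValueError, match="at least 32"):
        compute_psd(tr, segment_length=16)
    with pytest.raises(ValueError, match="exceeds"):
        compute_psd(tr, segment_length=4096)
    with pytest.raises(ValueError, match="overlap"):
        compute_psd(tr, segment_length=256, overlap=1.5)


# ----------------------------------------------------------- Lorentzian


def test_lorentzian_fit_exact_curve():
    f = np.geomspace(5.0, 1e4, 800)
    fc, a, b = 123.0, 2.5e-3, 4e-9
    s = a / (fc ** 2 + f ** 2) + b
    fit = fit_lorentzian(f, s)
    assert fit.corner_frequency == pytest.approx(fc, rel=1e-6)
    assert fit.amplitude == pytest.approx(a, rel=1e-6)
    assert fit.noise_floor == pytest.approx(b, rel=1e-5)
    assert fit.fit_residual < 1e-8
    assert not fit.boundary_flag


def test_lorentzian_fit_without_floor():
    f = np.geomspace(5.0, 1e4, 400)
    fc, a = 60.0, 1e-3
    s = a / (fc ** 2 + f ** 2)
    fit = fit_lorentzian(f, s, fit_floor=False)
    assert fit.corner_frequency == pytest.approx(fc, rel=1e-6)
    assert fit.noise_floor == 0.0


def test_lorentzian_white_spectrum_flags_boundary():
    f = np.geomspace(5.0, 1e4, 400)
    s = np.full_like(f, 1e-6)
    fit = fit_lorentzian(f, s)
    assert fit.boundary_flag


def test_lorentzian_too_few_bins():
    with pytest.raises(ValueError, match="at least 10"):
        fit_lorentzian(np.array([10.0, 20.0, 30.0]), np.ones(3))


# -------------------------------------------------- end-to-end recovery


def test_corner_frequency_recovered_within_ten_percent():
    spec = _fast_spec(f_c=50.0, duration=6.0, seed=7)
    trace, _ = make_ou_trace(spec)
    res = TrapTraceModel(trace).fit()
    assert res.corner_frequency == pytest.approx(spec.f_c, rel=0.10)
    assert not res.psd_fit.boundary_flag


def test_ou_variance_matches_lorentzian_area():
    """For the one-sided OU spectrum S(f) = A/(f_c^2+f^2) + B the OU
    variance equals (pi/2) A / f_c; the fitted parameters must reproduce
    the planted stationary variance."""
    spec = _fast_spec(f_c=80.0, duration=6.0, seed=13)
    trace, _ = make_ou_trace(spec)
    res = TrapTraceModel(trace).fit()
    fitted_var = (np.pi / 2) * res.psd_fit.amplitude / res.corner_frequency
    assert fitted_var == pytest.approx(spec.stationary_sd ** 2, rel=0.15)


def test_stiffer_trap_ordering():
    """Emulating increasing trap stiffness k (f_c ~ k, stationary SD
    ~ 1/sqrt(k)): fitted corner frequencies increase while normalized
    RMSD decreases, the anticorrelation the analysis is built around."""
    stiffness = [1.0, 2.5, 6.0]
    fcs, nrmsds = [], []
    for i, k in enumerate(stiffness):
        spec = _fast_spec(f_c=30.0 * k, stationary_sd=0.006 / np.sqrt(k),
                          seed=100 + i)
        res = TrapTraceModel(make_ou_trace(spec)[0]).fit()
        fcs.append(res.corner_frequency)
        nrmsds.append(res.nrmsd)
    assert np.all(np.diff(fcs) > 0)
    assert np.all(np.diff(nrmsds) < 0)


def test_model_raises_without_step():
    rng = np.random.default_rng(31)
    flat = TweezerTrace(1.0 + rng.normal(0, 0.001, 60_000), 10_000.0,
                        label="flat")
    with pytest.raises(ValueError, match="no trapping step"):
        TrapTraceModel(flat).fit()


def test_results_row_and_summary():
    trace, _ = make_ou_trace(_fast_spec(seed=17))
    res = TrapTraceModel(trace).fit()
    row = res.to_row()
    assert row["corner_frequency_hz"] == res.corner_frequency
    assert row["normalized_rmsd"] == res.nrmsd
    text = res.summary()
    assert "corner frequency" in text and "normalized RMSD" in text


# ------------------------------------------------------------------ I/O


def test_read_trace_two_column(tmp_path):
    trace, _ = make_ou_trace(_fast_spec(duration=0.5, step_time=0.2,
                                        sampling_rate=2_000.0))
    p = tmp_path / "trace.txt"
    np.savetxt(p, np.column_stack([trace.times(), trace.samples]))
    back = read_trace(p)
    assert back.sampling_rate == pytest.approx(trace.sampling_rate,
                                               rel=1e-6)
    assert np.allclose(back.samples, trace.samples)


def test_read_trace_single_column(tmp_path):
    p = tmp_path / "one.txt"
    np.savetxt(p, np.linspace(1, 2, 500))
    back = read_trace(p, sampling_rate=1_000.0)
    assert back.sampling_rate == 1_000.0
    with pytest.raises(ValueError, match="sampling_rate"):
        read_trace(p)


def test_read_trace_nonmonotonic_time(tmp_path):
    p = tmp_path / "bad.txt"
    np.savetxt(p, np.column_stack([[0.0, 0.2, 0.1], [1.0, 1.0, 1.0]]))
    with pytest.raises(ValueError, match="increasing"):
        read_trace(p)


def test_trace_validation():
    with pytest.raises(ValueError, match="positive"):
        TweezerTrace(np.ones(10), -1.0)
    with pytest.raises(ValueError, match="2 samples"):
        TweezerTrace(np.ones(1), 10.0)
    with pytest.raises(ValueError, match="non-finite"):
        TweezerTrace(np.array([1.0, np.nan, 2.0]), 10.0)
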