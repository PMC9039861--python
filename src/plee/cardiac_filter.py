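"""Spectral removal of cardiac oscillations from the oesophageal pressure.

The heart beats against the oesophagus, superimposing an oscillation at the
heart rate (and its harmonics) on the balloon signal.  Pleural pressure
carries no such component, so the oscillation is a measurement artifact and
may be removed.  This module does so with a comb of spectral notches: the
signal is Fourier-transformed, the bins within a half-width of each of the
first few harmonics of the heart rate are zeroed, and the signal is
transformed back.

A comb of narrow notches is preferred over a low-pass because respiratory
and cardiac bands can overlap at high respiratory rates; the half-width
(default 0.15 Hz) tolerates ordinary heart-rate variability within a
recording.  The filter operates on the unpadded signal, making it an exact
orthogonal projection: applying it twice equals applying it once, it is
linear, and the signal mean (DC bin) is untouched.  The price is spectral
leakage at the record edges, absorbed in practice by the notch width.

When the heart rate was not recorded alongside the pressure signal it can
be estimated from the spectrum of the oesophageal pressure itself
(:func:`estimate_cardiac_frequency`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EstimationFailedError

logger = logging.getLogger(__name__)

#: Plausible adult heart-rate band, Hz (40–180 bpm).
PHYSIOLOGIC_BAND = (0.67, 3.0)


@dataclass(frozen=True)
class CardiacFilterConfig:
    """Parameters of the cardiac notch comb.

    heart_rate_hz
        Fundamental cardiac frequency.  ``None`` means: estimate it from
        the signal (requires a detectable cardiac spectral peak).
    n_harmonics
        Number of harmonics to notch; the cardiac waveform is not
        sinusoidal, so the first few multiples of the heart rate carry
        power too.
    notch_halfwidth_hz
        Half-width of each notch; covers heart-rate variability and
        spectral leakage.
    physiologic_band
        Band searched when estimating the heart rate.
    """

    heart_rate_hz: float | None = None
    n_harmonics: int = 3
    notch_halfwidth_hz: float = 0.15
    physiologic_band: tuple[float, float] = PHYSIOLOGIC_BAND

    def __post_init__(self) -> None:
        if self.n_harmonics < 1:
            raise ConfigError("n_harmonics must be >= 1")
        if self.notch_halfwidth_hz <= 0:
            raise ConfigError("notch_halfwidth_hz must be > 0")


def estimate_cardiac_frequency(
    pes: np.ndarray,
    sampling_hz: float,
    band: tuple[float, float] = PHYSIOLOGIC_BAND,
    resp_period_s: float | None = None,
    min_peak_ratio: float = 3.0,
    min_amplitude_cmh2o: float = 0.1,
) -> float:
    """Estimate the heart rate (Hz) from the oesophageal pressure spectrum.

    The respiratory fundamental dominates the raw spectrum, so the signal is
    first detrended by subtracting a moving mean over one respiratory
    period (estimated from the dominant sub-cardiac spectral peak when not
    given).  The cardiac frequency is then the largest spectral peak within
    the physiologic band, required to stand at least ``min_peak_ratio``
    times above the median in-band power AND to imply an oscillation of at
    least ``min_amplitude_cmh2o`` — an absolute floor, since a cardiac
    oscillation far smaller than that would not be visible on the monitor
    either, and a relative test alone can latch onto numerical residue
    when no cardiac component exists at all.
    """
    pes = np.asarray(pes, dtype=float)
    n = pes.size
    if n < 10 * sampling_hz:
        raise ValueError("need at least 10 s of signal to estimate the heart rate")

    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_hz)
    if resp_period_s is None:
        # dominant component below the cardiac band, ignoring DC
        spec0 = np.abs(np.fft.rfft(pes - pes.mean()))
        sub = (freqs > 1.0 / (n / sampling_hz)) & (freqs < band[0])
        if sub.any() and spec0[sub].max() > 0:
            resp_period_s = 1.0 / float(freqs[sub][np.argmax(spec0[sub])])
        else:
            resp_period_s = 5.0  # nothing respiratory visible; a typical breath
    win = max(3, int(round(resp_period_s * sampling_hz)))
    win = min(win, n)
    kernel = np.ones(win) / win
    moving_mean = np.convolve(np.pad(pes, win // 2, mode="edge"), kernel, mode="same")
    moving_mean = moving_mean[win // 2 : win // 2 + n]
    detrended = pes - moving_mean
    # the moving mean nulls the respiratory wave only in the interior;
    # drop one window at each end so edge leakage cannot pose as a peak
    if n > 4 * win:
        detrended = detrended[win:-win]
    m = detrended.size

    freqs = np.fft.rfftfreq(m, d=1.0 / sampling_hz)
    window = np.hanning(m)  # tame leakage so peaks stay within ~1 bin
    power = np.abs(np.fft.rfft(detrended * window)) ** 2
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    # A non-sinusoidal respiratory wave has harmonics inside the cardiac
    # band; a spectral peak sitting on a multiple of the respiratory
    # fundamental cannot be told apart from one, so those frequencies are
    # not cardiac candidates.  (A heart rate that truly coincides with a
    # respiratory harmonic must be supplied by the caller.)
    f_resp = 1.0 / resp_period_s
    tol = max(0.02, sampling_hz / m)
    harmonic_no = np.rint(freqs / f_resp)
    on_harmonic = np.abs(freqs - harmonic_no * f_resp) <= tol
    in_band &= ~on_harmonic
    band_power = power[in_band]
    if band_power.size == 0:
        raise ValueError("physiologic band empty at this sampling rate / length")
    peak_idx = int(np.argmax(band_power))
    floor = float(np.median(band_power))
    # |rfft| of a Hann-windowed sinusoid of amplitude A peaks at A*m/4
    peak_amplitude = 4.0 * np.sqrt(band_power[peak_idx]) / m
    if (
        floor <= 0
        or band_power[peak_idx] < min_peak_ratio * floor
        or peak_amplitude < min_amplitude_cmh2o
    ):
        raise EstimationFailedError(
            "no cardiac spectral peak stands out in the physiologic band; "
            "supply the heart rate explicitly"
        )
    f_cardiac = float(freqs[in_band][peak_idx])
    logger.info("estimated cardiac frequency %.3f Hz (%.0f bpm)", f_cardiac, 60 * f_cardiac)
    return f_cardiac


def remove_cardiac_oscillation(
    pes: np.ndarray,
    sampling_hz: float,
    cfg: CardiacFilterConfig | None = None,
) -> np.ndarray:
    """Notch out the cardiac fundamental and harmonics from a pressure trace.

    Zeroes the spectral content within ``notch_halfwidth_hz`` of each of the
    first ``n_harmonics`` multiples of the heart rate and inverse-transforms.
    Output length equals input length; the mean is preserved exactly (the
    DC bin is never inside a notch — a configuration placing it there is
    rejected).
    """
    cfg = cfg or CardiacFilterConfig()
    pes = np.asarray(pes, dtype=float)
    n = pes.size
    f0 = cfg.heart_rate_hz
    if f0 is None:
        f0 = estimate_cardiac_frequency(pes, sampling_hz, cfg.physiologic_band)
    if f0 - cfg.notch_halfwidth_hz <= 0:
        raise ConfigError(
            f"notch at {f0:g} Hz with half-width {cfg.notch_halfwidth_hz:g} Hz "
            "would reach 0 Hz and destroy the signal baseline"
        )

    spec = np.fft.rfft(pes)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_hz)
    mask = np.zeros(freqs.size, dtype=bool)
    for m in range(1, cfg.n_harmonics + 1):
        centre = m * f0
        mask |= np.abs(freqs - centre) <= cfg.notch_halfwidth_hz
    spec[mask] = 0.0
    out = np.fft.irfft(spec, n=n)
    return out
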