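"""Spectrograms and separation of rhythmic from arrhythmic spectral content.

Power spectra are estimated with 50%-overlapping 8-s Hanning windows over
0-300 Hz on a 0.5 Hz grid.  The arrhythmic (fractal, 1/f-like) component is
isolated by irregular resampling (IRASA): a power-law spectrum is invariant
under compressing/stretching the time axis by reciprocal factors, while any
narrowband rhythm is displaced, so the median across resampling factors of
the geometric mean of up/down-resampled spectra estimates the fractal part.
Normalizing the total spectrum to this estimate yields ``oscillatory_db``
("dB_fractal"), a measure that emphasizes truly rhythmic activity:

    oscillatory_db(f) = 10 * log10( total(f) / fractal(f) )
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

WINDOW_S = 8.0          # Hanning window length (s)
GRID_DF = 0.5           # output frequency resolution (Hz)
F_MAX = 300.0           # upper edge of the analysis grid (Hz)

#: Default irregular-resampling factors (reciprocal pairs are implied).
DEFAULT_H_SET = tuple(np.round(np.arange(1.10, 1.901, 0.05), 2))


@dataclass
class Spectrogram:
    """Time-frequency power (time bins x frequency bins, uV^2/Hz)."""

    power: np.ndarray
    freqs: np.ndarray   # Hz, 0..300 at 0.5
    times: np.ndarray   # window centers, s
    source: str = ""

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("frequency and time grids must be strictly increasing")

    def mean_spectrum(self, t0: float | None = None, t1: float | None = None
                      ) -> np.ndarray:
        """Time-averaged power spectrum over window centers in [t0, t1)."""
        sel = np.ones(len(self.times), dtype=bool)
        if t0 is not None:
            sel &= self.times >= t0
        if t1 is not None:
            sel &= self.times < t1
        if not sel.any():
            raise ValueError("no spectrogram bins in requested window")
        return self.power[sel].mean(axis=0)


@dataclass
class FractalDecomposition:
    """Total and fractal power spectra plus their dB ratio on one grid."""

    total: np.ndarray
    fractal: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.fractal <= 0):
            raise ValueError("fractal estimate must be strictly positive")

    @property
    def oscillatory_db(self) -> np.ndarray:
        return 10.0 * np.log10(self.total / self.fractal)

    def band(self, f_lo: float, f_hi: float) -> tuple[np.ndarray, np.ndarray]:
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return self.freqs[sel], self.oscillatory_db[sel]


def _aggregate_to_grid(freqs_native: np.ndarray, power_native: np.ndarray,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-pool native 0.125 Hz Welch bins onto the 0.5 Hz output grid.

    Output bin j is centered on j*0.5 Hz and averages the native bins within
    +-0.25 Hz of the center (4 bins; fewer at the grid edges).
    """
    df_native = freqs_native[1] - freqs_native[0]
    n_out = int(round(F_MAX / GRID_DF)) + 1
    freqs_out = np.arange(n_out) * GRID_DF
    # native index range for output bin j: centers within [f_j-0.25, f_j+0.25)
    lo = np.ceil((freqs_out - GRID_DF / 2) / df_native - 1e-9).astype(int)
    hi = np.ceil((freqs_out + GRID_DF / 2) / df_native - 1e-9).astype(int)
    lo = np.clip(lo, 0, len(freqs_native))
    hi = np.clip(hi, 0, len(freqs_native))
    power_native = np.asarray(power_native)
    csum = np.concatenate([np.zeros(power_native.shape[:-1] + (1,)),
                           np.cumsum(power_native, axis=-1)], axis=-1)
    counts = np.maximum(hi - lo, 1)
    pooled = (csum[..., hi] - csum[..., lo]) / counts
    return freqs_out, pooled


def _welch_native(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(WINDOW_S * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal too short: need at least {WINDOW_S:g} s ({nperseg} samples), "
            f"got {x.shape[-1]}")
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend=False)


def compute_spectrogram(signal: np.ndarray, fs: float, source: str = ""
                        ) -> Spectrogram:
    """8-s Hanning, 50%-overlap spectrogram on the 0-300 Hz, 0.5 Hz grid."""
    x = np.asarray(signal, dtype=np.float64)
    nperseg = int(round(WINDOW_S * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"signal too short: need at least {WINDOW_S:g} s ({nperseg} samples), "
            f"got {x.shape[-1]}")
    f, t, p = sps.spectrogram(x, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend=False,
                              scaling="density")
    freqs_out, pooled = _aggregate_to_grid(f, p.T)
    return Spectrogram(power=pooled, freqs=freqs_out, times=t, source=source)


def welch_spectrum(signal: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with the standard window settings, pooled to the 0.5 Hz grid."""
    f, p = _welch_native(np.asarray(signal, dtype=np.float64), fs)
    return _aggregate_to_grid(f, p)


def irasa_decompose(signal_segment: np.ndarray, fs: float,
                    h_set: tuple[float, ...] | None = None,
                    trim_s: float = 1.0) -> FractalDecomposition:
    """Separate fractal and oscillatory power by irregular resampling.

    For each factor ``h`` the segment is resampled by ``h`` and ``1/h``
    (rational polyphase); treating the resampled series as if still sampled
    at ``fs`` shifts rhythmic peaks in frequency while leaving a power law
    unchanged, so ``sqrt(S_h * S_1/h)`` cancels rhythms.  The fractal
    estimate is the median of that geometric mean across ``h_set``.

    ``trim_s`` seconds are dropped from each end of every resampled series
    to suppress filter edge effects.
    """
    if h_set is None:
        h_set = DEFAULT_H_SET
    if len(h_set) == 0:
        raise ValueError("h_set must not be empty")
    x = np.asarray(signal_segment, dtype=np.float64)
    nperseg = int(round(WINDOW_S * fs))
    ntrim = int(round(trim_s * fs))

    f_native, total_native = _welch_native(x, fs)
    geo_means = []
    for h in h_set:
        frac = Fraction(h).limit_denominator(50)
        up = sps.resample_poly(x, frac.numerator, frac.denominator)
        dn = sps.resample_poly(x, frac.denominator, frac.numerator)
        if ntrim:
            up = up[ntrim:-ntrim]
            dn = dn[ntrim:-ntrim]
        if min(len(up), len(dn)) < nperseg:
            raise ValueError(
                "segment too short for IRASA with the requested h_set: "
                f"need >= {WINDOW_S * max(h_set) + 2 * trim_s:g} s")
        _, p_up = _welch_native(up, fs)
        _, p_dn = _welch_native(dn, fs)
        geo_means.append(np.sqrt(p_up * p_dn))
    fractal_native = np.median(geo_means, axis=0)

    freqs, total = _aggregate_to_grid(f_native, total_native)
    _, fractal = _aggregate_to_grid(f_native, fractal_native)
    # guard the DC/edge bins where the welch estimate can underflow
    floor = np.finfo(float).tiny
    return FractalDecomposition(total=np.maximum(total, floor),
                                fractal=np.maximum(fractal, floor), freqs=freqs)


def structure_average_spectrum(oscillatory_db_spectra: list[np.ndarray],
                               freqs: np.ndarray | None = None) -> np.ndarray:
    """Mean oscillatory_db spectrum across electrode pairs of one structure."""
    if not oscillatory_db_spectra:
        raise ValueError("need at least one spectrum")
    lengths = {np.shape(s)[-1] for s in oscillatory_db_spectra}
    if len(lengths) != 1:
        raise ValueError("spectra are on different frequency grids")
    return np.mean(oscillatory_db_spectra, axis=0)


def block_decompositions(signal: np.ndarray, fs: float, block_s: float = 60.0,
                         h_set: tuple[float, ...] | None = None
                         ) -> list[FractalDecomposition]:
    """IRASA decomposition of consecutive non-overlapping blocks."""
    n_block = int(round(block_s * fs))
    n = len(signal) // n_block
    if n == 0:
        raise ValueError(f"signal shorter than one {block_s:g}-s block")
    return [irasa_decompose(signal[i * n_block:(i + 1) * n_block], fs, h_set=h_set)
            for i in range(n)]
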