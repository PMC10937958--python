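"""Cross-structure phase coupling of detected HFOs (von Mises kappa).

Phase is extracted from bipolar traces by a 4th-order zero-phase band-pass
(session peak frequency +/- 10 Hz, matching the 20 Hz band-power window)
followed by the analytic-signal angle.  Phase differences between two
structures are collected only from analysis blocks where the HFO detector
fired in both ("detected in parallel"), decimated to one sample per
oscillation cycle to reduce serial dependence, and summarized by the
concentration kappa of a fitted circular normal (von Mises) distribution;
sigma^2 = 1/kappa, so higher kappa means tighter phase locking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

KAPPA_CAP = 500.0


@dataclass
class PhaseSeries:
    """Instantaneous band phase with a per-sample validity mask."""

    phase: np.ndarray          # radians, wrapped to (-pi, pi]
    mask: np.ndarray           # bool, True during HFO-detected blocks
    fs: float
    center_f: float

    def __post_init__(self) -> None:
        if self.phase.shape != self.mask.shape:
            raise ValueError("phase and mask must have the same shape")


@dataclass
class PhaseDistribution:
    """Circular sample summary: mean direction, resultant length, kappa."""

    n: int
    mu: float                  # circular mean (rad)
    resultant: float           # mean resultant length R in [0, 1]
    kappa: float

    @property
    def circular_variance(self) -> float:
        return 1.0 - self.resultant


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))


def extract_band_phase(signal: np.ndarray, fs: float, center_f: float,
                       half_width: float = 10.0,
                       mask: np.ndarray | None = None) -> PhaseSeries:
    """Zero-phase band-pass + analytic signal phase around ``center_f``."""
    lo, hi = center_f - half_width, center_f + half_width
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band [{lo}, {hi}] Hz outside (0, {fs / 2}) Hz")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, np.asarray(signal, float))
    phase = np.angle(sps.hilbert(filtered))
    if mask is None:
        mask = np.ones_like(phase, dtype=bool)
    return PhaseSeries(phase=phase, mask=np.asarray(mask, bool), fs=fs,
                       center_f=center_f)


def block_mask(n_samples: int, fs: float, block_s: float,
               detected_blocks: list[int]) -> np.ndarray:
    """Validity mask that is True inside the listed analysis blocks."""
    mask = np.zeros(n_samples, dtype=bool)
    nb = int(round(block_s * fs))
    for b in detected_blocks:
        mask[b * nb:(b + 1) * nb] = True
    return mask


def phase_differences(series_a: PhaseSeries, series_b: PhaseSeries,
                      per_cycle: bool = True) -> np.ndarray:
    """Wrapped phase differences a - b on the joint validity mask.

    With ``per_cycle`` (default) the differences are decimated to one
    sample per oscillation cycle (step fs / center_f) before kappa
    estimation, since the maximum-likelihood theory assumes independent
    draws.  Returns an empty array when the masks never overlap.
    """
    if series_a.fs != series_b.fs:
        raise ValueError("sampling rates differ")
    joint = series_a.mask & series_b.mask
    diffs = wrap_phase(series_a.phase[joint] - series_b.phase[joint])
    if per_cycle and diffs.size:
        step = max(int(round(series_a.fs / series_a.center_f)), 1)
        diffs = diffs[::step]
    return diffs


def _kappa_from_resultant(r: float) -> float:
    """Fisher's piecewise approximation to the ML inverse of A(kappa)=R."""
    if r < 0.53:
        k = 2 * r + r ** 3 + 5 * r ** 5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        denom = r ** 3 - 4 * r ** 2 + 3 * r
        k = 1.0 / denom if denom > 0 else KAPPA_CAP
    return float(min(max(k, 0.0), KAPPA_CAP))


def estimate_von_mises(sample: np.ndarray) -> PhaseDistribution:
    """Fit a circular normal: mu = circular mean, kappa from R (capped at 500)."""
    x = np.asarray(sample, float)
    if x.size < 10:
        raise ValueError(f"need at least 10 phase samples, got {x.size}")
    z = np.mean(np.exp(1j * x))
    r = float(np.abs(z))
    return PhaseDistribution(n=x.size, mu=float(np.angle(z)), resultant=r,
                             kappa=_kappa_from_resultant(r))


def coupling_change_matrix(condition_kappa: pd.DataFrame,
                           reference_kappa: pd.DataFrame) -> pd.DataFrame:
    """Elementwise delta-kappa (condition - reference) over structure pairs.

    Both inputs are square DataFrames indexed by structure with identical
    index/columns; missing (NaN) cells propagate as missing, never zero.
    """
    if not condition_kappa.index.equals(reference_kappa.index) or \
            not condition_kappa.columns.equals(reference_kappa.columns):
        raise ValueError("condition and reference cover different pair sets")
    return condition_kappa - reference_kappa


def pooled_pair_kappa(phase_series: dict[str, PhaseSeries],
                      min_n: int = 10) -> pd.DataFrame:
    """kappa matrix over all structure pairs from pooled phase differences.

    ``phase_series`` maps structure -> PhaseSeries (already masked to
    detected blocks).  The diagonal is within-structure coupling only when
    multiple series per structure are supplied elsewhere; here it is the
    degenerate self-comparison and set to the cap.
    """
    structures = sorted(phase_series)
    mat = pd.DataFrame(np.nan, index=structures, columns=structures)
    for i, a in enumerate(structures):
        for b in structures[i:]:
            if a == b:
                mat.loc[a, b] = KAPPA_CAP
                continue
            d = phase_differences(phase_series[a], phase_series[b])
            if d.size >= min_n:
                k = estimate_von_mises(d).kappa
                mat.loc[a, b] = k
                mat.loc[b, a] = k
    return mat


def joint_frequency_histogram(block_fits: pd.DataFrame,
                              bin_edges: np.ndarray | None = None
                              ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """2-D histogram of co-occurring peak frequencies across structures.

    For every analysis block where two or more structures have a positive
    detection, all ordered structure pairs contribute their fitted (B_i,
    B_j).  Returns (counts, bin_edges, pair_table).
    """
    det = block_fits.loc[block_fits["detected"]]
    pairs = []
    for (_, block), sub in det.groupby(["condition", "block"]):
        rows = sub.reset_index(drop=True)
        for i in range(len(rows)):
            for j in range(len(rows)):
                if i != j and rows.loc[i, "structure"] != rows.loc[j, "structure"]:
                    pairs.append((rows.loc[i, "B"], rows.loc[j, "B"]))
    table = pd.DataFrame(pairs, columns=["B_1", "B_2"])
    if bin_edges is None:
        bin_edges = np.arange(115.0, 171.0, 1.0)
    if table.empty:
        counts = np.zeros((len(bin_edges) - 1, len(bin_edges) - 1))
    else:
        counts, *_ = np.histogram2d(table["B_1"], table["B_2"],
                                    bins=[bin_edges, bin_edges])
    return counts, bin_edges, table


def diagonal_mass_fraction(table: pd.DataFrame, tol_hz: float = 2.0) -> float:
    """Fraction of co-detections whose peak frequencies agree within tol."""
    if table.empty:
        return float("nan")
    return float(np.mean(np.abs(table["B_1"] - table["B_2"]) <= tol_hz))
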