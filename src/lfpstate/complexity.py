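"""Permutation entropy of LFP time series.

Each window of ``m`` consecutive samples (no embedding delay) is mapped to
its ordinal pattern — the permutation that sorts it, ties broken by order of
occurrence — and the Shannon entropy of the pattern distribution,
``-sum p_i ln p_i``, is the permutation entropy.  With order 6 there are
720 possible patterns; normalized PE divides by ln(720) so 1 means all
patterns equally likely (temporally disordered signal) and 0 means a single
pattern (e.g. a monotone ramp).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EntropyConfig:
    order: int = 6
    delay: int = 1
    window_len: int = 30_000       # samples (15 s at 2 kHz)
    hop: int = 2_000               # samples between window starts (1 s)
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.order < 2:
            raise ValueError("order must be >= 2")
        if self.hop < 1 or self.delay < 1:
            raise ValueError("hop and delay must be >= 1")
        if self.window_len < math.factorial(self.order) * 5:
            warnings.warn(
                f"window_len {self.window_len} < 5 * {self.order}! patterns; "
                "pattern frequencies will be undersampled")


def ordinal_pattern_index(window: np.ndarray) -> int:
    """Lehmer-code index of the rank permutation of ``m`` values.

    Strictly increasing values give 0, strictly decreasing give m!-1.  Ties
    are broken stably (first occurrence ranks lower).  Non-finite values are
    rejected.
    """
    w = np.asarray(window, dtype=float)
    if not np.isfinite(w).all():
        raise ValueError("window contains non-finite values")
    perm = np.argsort(w, kind="stable")
    m = len(perm)
    idx = 0
    for i in range(m):
        smaller_after = int(np.sum(perm[i + 1:] < perm[i]))
        idx += smaller_after * math.factorial(m - 1 - i)
    return idx


def _pattern_codes(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    """Vectorized Lehmer codes for every length-m window of x (stride 1)."""
    n = len(x) - (m - 1) * delay
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    idx = np.arange(n)[:, None] + np.arange(m)[None, :] * delay
    W = x[idx]
    perm = np.argsort(W, axis=1, kind="stable")
    codes = np.zeros(n, dtype=np.int64)
    for i in range(m):
        smaller_after = np.zeros(n, dtype=np.int64)
        for j in range(i + 1, m):
            smaller_after += (perm[:, j] < perm[:, i])
        codes += smaller_after * math.factorial(m - 1 - i)
    return codes


def permutation_entropy_window(samples: np.ndarray,
                               config: EntropyConfig | None = None) -> float:
    """Permutation entropy of one window (nats, or normalized by ln(m!))."""
    config = config or EntropyConfig()
    x = np.asarray(samples, dtype=float)
    finite = np.isfinite(x)
    if not finite.all():
        x = x[finite]
    codes = _pattern_codes(x, config.order, config.delay)
    if codes.size == 0:
        raise ValueError("window shorter than one ordinal pattern")
    counts = np.bincount(codes)
    p = counts[counts > 0] / codes.size
    pe = float(-np.sum(p * np.log(p)))
    if pe == 0.0:
        warnings.warn("single ordinal pattern in window (constant/monotone input)")
    if config.normalize:
        pe /= math.log(math.factorial(config.order))
    return pe


def permutation_entropy_series(signal: np.ndarray,
                               epochs: pd.DataFrame,
                               fs: float,
                               config: EntropyConfig | None = None
                               ) -> pd.DataFrame:
    """Sliding-window PE per condition epoch; one row per window.

    ``epochs`` has columns (label, start_s, end_s); windows never straddle
    an epoch boundary.  Epochs shorter than one window yield no rows (the
    caller sees the condition as undefined).
    """
    config = config or EntropyConfig()
    rows = []
    for _, ep in epochs.iterrows():
        i0 = int(np.floor(ep.start_s * fs))
        i1 = int(np.floor(ep.end_s * fs))
        for w0 in range(i0, i1 - config.window_len + 1, config.hop):
            pe = permutation_entropy_window(
                signal[w0:w0 + config.window_len], config)
            rows.append({"condition": ep.label, "window_start_s": w0 / fs,
                         "pe": pe})
    return pd.DataFrame(rows, columns=["condition", "window_start_s", "pe"])


def mean_entropy_per_condition(pe_windows: pd.DataFrame) -> pd.Series:
    """One representative entropy value per condition (mean over windows)."""
    if pe_windows.empty:
        return pd.Series(dtype=float)
    return pe_windows.groupby("condition")["pe"].mean()
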