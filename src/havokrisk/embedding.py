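"""Hankel delay embedding and its SVD coordinates.

A scalar series x(t) is stacked into a Hankel matrix H with d rows, each
row one sample delayed relative to the previous, H[i, j] = x[i + j]. The
economy SVD H = U S V' yields:

- U columns: delay-window basis shapes (polynomial/oscillatory modes whose
  dominant period decreases with the column index);
- V columns: the delay-coordinate time series, indexed by window start
  time (row t of V corresponds to the window x[t : t + d]).

The line-length envelope of a (forcing) coordinate - the trailing-window
sum of absolute first differences - tracks the gradual growth of its
amplitude without looking ahead.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

__all__ = [
    "DelayEmbedding",
    "ForcingSignal",
    "build_hankel",
    "svd_embedding",
    "delay_embed",
    "dominant_period",
    "line_length_envelope",
    "forcing_signal",
]


@dataclasses.dataclass
class DelayEmbedding:
    """Hankel matrix and (optionally) its truncated SVD.

    ``time_offset`` records the alignment convention: row ``t`` of V maps to
    source sample ``t`` (window-start alignment).
    """

    d: int
    H: np.ndarray
    U: np.ndarray | None = None
    S: np.ndarray | None = None
    V: np.ndarray | None = None
    k: int | None = None
    sign_flips: np.ndarray | None = None
    time_offset: str = "window_start"

    @property
    def n_windows(self) -> int:
        return self.H.shape[1]


def build_hankel(series: np.ndarray, d: int) -> DelayEmbedding:
    """Delay-embed ``series`` into a d x (N - d + 1) Hankel matrix."""
    x = np.asarray(series, dtype=float).ravel()
    if d < 1:
        raise ValueError("embedding depth d must be >= 1")
    if x.size < d:
        raise ValueError(f"series length {x.size} < embedding depth {d}")
    H = scipy.linalg.hankel(x[:d], x[d - 1 :])
    return DelayEmbedding(d=d, H=H)


def svd_embedding(emb: DelayEmbedding, k: int | None = None) -> DelayEmbedding:
    """Economy SVD of the Hankel matrix, truncated to ``k`` components.

    Sign convention: each (u_r, v_r) pair is flipped so that the largest-
    magnitude element of u_r is positive; SVD signs are otherwise arbitrary
    and would break regression tests.
    """
    k = emb.d if k is None else int(k)
    if k > emb.d or k < 1:
        raise ValueError(f"truncation k={k} outside [1, d={emb.d}]")
    U, S, Vt = np.linalg.svd(emb.H, full_matrices=False)
    U, S, V = U[:, :k], S[:k], Vt[:k].T
    flips = np.ones(k)
    for j in range(k):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] *= -1.0
            V[:, j] *= -1.0
            flips[j] = -1.0
    return dataclasses.replace(emb, U=U, S=S, V=V, k=k, sign_flips=flips)


def delay_embed(series: np.ndarray, d: int = 100, k: int = 22) -> DelayEmbedding:
    """Convenience: Hankel build + truncated SVD in one call."""
    return svd_embedding(build_hankel(series, d), k)


def dominant_period(u_col: np.ndarray, sample_hours: float = 1.0) -> float:
    """Period (hours) of the largest nonzero-frequency FFT peak of a column.

    The peak bin is refined by quadratic interpolation of the magnitude
    spectrum. Returns ``inf`` when the DC bin dominates (slower than the
    window can resolve); raises on an all-zero column.
    """
    u = np.asarray(u_col, dtype=float).ravel()
    n = u.size
    if n < 4:
        raise ValueError("column too short for a frequency estimate")
    if not np.any(u):
        raise ValueError("all-zero column has no dominant period")
    mag = np.abs(np.fft.rfft(u))
    j = int(np.argmax(mag[1:])) + 1
    if mag[0] >= mag[j]:
        return float("inf")
    # parabolic refinement around the peak bin
    delta = 0.0
    if 1 <= j - 1 and j + 1 < mag.size:
        denom = mag[j - 1] - 2 * mag[j] + mag[j + 1]
        if abs(denom) > 1e-30:
            delta = 0.5 * (mag[j - 1] - mag[j + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
    freq = (j + delta) / (n * sample_hours)
    return 1.0 / freq


def line_length_envelope(
    v: np.ndarray, window_hours: int = 72
) -> tuple[np.ndarray, np.ndarray]:
    """Trailing line-length envelope and its z-scored version.

    ``line_length[t] = sum_{i=t-w+1..t} |v(i) - v(i-1)|`` over the trailing
    window of ``w = window_hours`` first differences (causal: no look-ahead,
    so the envelope can flag forcing that precedes events). The first ``w``
    samples are a warm-up with partial sums. The normalization is a z-score
    over the post-warm-up span, so "normalized line length > 0" reads
    "above its mean".
    """
    v = np.asarray(v, dtype=float).ravel()
    w = int(window_hours)
    if v.size <= w:
        raise ValueError(f"series of {v.size} samples shorter than window {w}")
    diffs = np.abs(np.diff(v))
    csum = np.concatenate([[0.0], np.cumsum(diffs)])
    t = np.arange(v.size)
    ll = csum[t] - csum[np.maximum(t - w, 0)]
    steady = ll[w:]
    sd = steady.std()
    if sd < 1e-12:
        nll = np.zeros_like(ll)
    else:
        nll = (ll - steady.mean()) / sd
    return ll, nll


@dataclasses.dataclass
class ForcingSignal:
    """A forcing coordinate v_r with its line-length amplitude envelope."""

    r: int
    v_r: np.ndarray
    line_length: np.ndarray
    normalized_line_length: np.ndarray
    window_hours: int
    warmup_mask: np.ndarray

    @property
    def active(self) -> np.ndarray:
        """High-forcing indicator: normalized line length above its mean."""
        return self.normalized_line_length > 0


def forcing_signal(
    emb: DelayEmbedding, r: int, window_hours: int = 72
) -> ForcingSignal:
    """Extract column ``r`` (1-based) of V as a forcing signal."""
    if emb.V is None:
        raise ValueError("run svd_embedding first")
    if not 1 <= r <= emb.k:
        raise ValueError(f"forcing index r={r} outside [1, k={emb.k}]")
    v = emb.V[:, r - 1]
    ll, nll = line_length_envelope(v, window_hours)
    warmup = np.arange(v.size) < window_hours
    return ForcingSignal(r, v, ll, nll, int(window_hours), warmup)
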