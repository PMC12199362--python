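"""Intermittently forced linear model of the delay coordinates.

The leading r-1 delay coordinates are modelled as a discrete-time linear
system driven by the low-energy r-th coordinate:

    V(t+1) = A V(t) + B V_r(t)

with V(t) = [V_1(t) ... V_{r-1}(t)]^T, the forcing V_r treated as an
exogenous input, and (A, B) estimated by plain least squares on a training
window (default six months = 4,380 h). Once fitted, the system is rolled
forward from the last training state using a known (or streamed) future
forcing, and the fit is scored per dimension as 1/MSE.

The forcing can also be recovered from a streaming series without a new
SVD: since V = H' U diag(S)^-1, the sliding inner product of the series
with u_r scaled by 1/sigma_r reproduces V_r exactly on the training span.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .embedding import DelayEmbedding

__all__ = [
    "HavokSystem",
    "HavokSimulation",
    "TRAIN_HOURS_SIX_MONTHS",
    "fit_havok",
    "simulate_havok",
    "predict_test_span",
    "streaming_forcing",
    "prediction_accuracy",
    "sweep_forcing_accuracy",
]

TRAIN_HOURS_SIX_MONTHS = 4380  # 365.25 / 2 * 24, rounded


@dataclasses.dataclass
class HavokSystem:
    """Fitted state matrix A ((r-1) x (r-1)), input column B, and metadata."""

    A: np.ndarray
    B: np.ndarray
    r: int
    train_span: tuple[int, int]
    fit_residual: np.ndarray  # per-dimension RMSE on the training span
    condition_number: float
    initial_condition: str = "last_training_state"


@dataclasses.dataclass
class HavokSimulation:
    """Forward simulation output; ``diverged_at`` flags a non-finite state."""

    V_pred: np.ndarray
    diverged_at: int | None = None


def _column_names(r: int) -> list[str]:
    return [f"state V_{j}" for j in range(1, r)] + [f"forcing V_{r}"]


def fit_havok(
    V: np.ndarray,
    r: int,
    train_span: tuple[int, int] | None = None,
) -> HavokSystem:
    """Least-squares fit of V(t+1) = A V(t) + B V_r(t) on ``train_span``.

    The regressor is the stacked [V_1..V_{r-1}, V_r](t); rank deficiency is
    detected from its singular values and reported with the offending
    columns named. No regularization: the model is a plain discrete-time
    least-squares system identification.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] < r:
        raise ValueError(f"V must have at least r={r} columns")
    t0, t1 = (0, V.shape[0]) if train_span is None else map(int, train_span)
    if not 0 <= t0 < t1 <= V.shape[0]:
        raise ValueError(f"train_span {t0, t1} outside V index range")
    n = t1 - t0 - 1
    if n <= 10 * r:
        raise ValueError(
            f"training span of {n} transitions too short (need > {10 * r} = 10*r)"
        )
    X = np.column_stack([V[t0 : t1 - 1, : r - 1], V[t0 : t1 - 1, r - 1]])
    Y = V[t0 + 1 : t1, : r - 1]

    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] <= sv[0] * 1e-12:
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        rank = int(np.sum(sv > sv[0] * 1e-12))
        names = _column_names(r)
        bad = sorted(names[i] for i in piv[rank:])
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor; deficient columns: {', '.join(bad)}"
        )
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    A = coef[: r - 1].T
    B = coef[r - 1].copy()
    resid = Y - X @ coef
    rmse = np.sqrt(np.mean(resid**2, axis=0))
    return HavokSystem(
        A=A,
        B=B,
        r=r,
        train_span=(t0, t1),
        fit_residual=rmse,
        condition_number=float(sv[0] / sv[-1]),
    )


def simulate_havok(
    sys: HavokSystem, v0: np.ndarray, forcing: np.ndarray
) -> HavokSimulation:
    """Roll the fitted system forward from state ``v0`` under ``forcing``.

    Output row t is the state after t+1 updates, i.e. the prediction for
    source time ``start + t + 1`` when ``v0`` is the state at ``start`` and
    ``forcing[t]`` the input at ``start + t``. If the state becomes
    non-finite (unstable A over a long horizon), the partial trajectory is
    returned with the divergence index set.
    """
    v = np.asarray(v0, dtype=float).ravel()
    if v.size != sys.r - 1:
        raise ValueError(f"v0 must have length r-1 = {sys.r - 1}")
    f = np.asarray(forcing, dtype=float).ravel()
    out = np.empty((f.size, sys.r - 1))
    for t in range(f.size):
        v = sys.A @ v + sys.B * f[t]
        if not np.all(np.isfinite(v)):
            out[t:] = np.nan
            return HavokSimulation(V_pred=out, diverged_at=t)
        out[t] = v
    return HavokSimulation(V_pred=out)


def predict_test_span(
    sys: HavokSystem, V: np.ndarray, forcing: np.ndarray | None = None
) -> tuple[HavokSimulation, np.ndarray]:
    """Simulate the span after training and pair it with the held-out truth.

    The initial condition is the last training-span state. ``forcing``
    defaults to the true future V_r; pass a surrogate (e.g. phase-
    randomized) series of the same length for null comparisons.
    """
    V = np.asarray(V, dtype=float)
    _, t1 = sys.train_span
    if t1 >= V.shape[0]:
        raise ValueError("no samples after the training span")
    true_f = V[t1 - 1 : -1, sys.r - 1]
    f = true_f if forcing is None else np.asarray(forcing, dtype=float).ravel()
    if f.size != true_f.size:
        raise ValueError(f"forcing must cover the test span ({true_f.size} samples)")
    sim = simulate_havok(sys, V[t1 - 1, : sys.r - 1], f)
    return sim, V[t1:, : sys.r - 1]


def streaming_forcing(
    u_r: np.ndarray,
    sigma_r: float,
    series: np.ndarray,
    align: str = "start",
) -> np.ndarray:
    """Extract V_r from a streaming series by convolution with mode u_r.

    The sliding inner product (cross-correlation, no kernel flip) of the
    series with u_r, scaled by 1/sigma_r. With ``align="start"`` output
    index t corresponds to the Hankel column whose window starts at t - the
    unique convention under which the output equals the SVD column V_r
    exactly. With ``align="end"`` the output is padded with ``d - 1``
    leading NaNs so index t only uses samples up to and including t
    (strictly causal, for forecasting features).
    """
    u = np.asarray(u_r, dtype=float).ravel()
    if sigma_r < 1e-12:
        raise ValueError("singular value below 1e-12; mode not identifiable")
    x = np.asarray(series, dtype=float).ravel()
    if x.size < u.size:
        raise ValueError("series shorter than the embedding depth")
    v = np.convolve(x, u[::-1], mode="valid") / sigma_r
    if align == "start":
        return v
    if align == "end":
        return np.concatenate([np.full(u.size - 1, np.nan), v])
    raise ValueError(f"unknown align {align!r}")


def prediction_accuracy(
    V_pred: np.ndarray,
    V_true: np.ndarray,
    dims: list[int] | None = None,
) -> np.ndarray:
    """Per-dimension 1/MSE between predicted and true coordinates.

    ``dims`` are 1-based coordinate indices (default: the leading three, or
    fewer if the system is smaller). A zero MSE is reported as ``inf``.
    """
    P = np.atleast_2d(np.asarray(V_pred, dtype=float))
    T = np.atleast_2d(np.asarray(V_true, dtype=float))
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {T.shape}")
    if dims is None:
        dims = list(range(1, min(3, P.shape[1]) + 1))
    cols = [d - 1 for d in dims]
    if any(c < 0 or c >= P.shape[1] for c in cols):
        raise ValueError(f"dims {dims} outside 1..{P.shape[1]}")
    mse = np.mean((P[:, cols] - T[:, cols]) ** 2, axis=0)
    with np.errstate(divide="ignore"):
        return np.where(mse > 0, 1.0 / np.where(mse > 0, mse, 1.0), np.inf)


def lobe_switch_enrichment(
    series: np.ndarray,
    emb: DelayEmbedding,
    r: int = 15,
    pre_window: int = 25,
    quantile: float = 0.95,
    n_permutations: int = 100,
    seed: int = 0,
) -> dict:
    """Test whether forcing bursts precede attractor lobe switches.

    A lobe switch is a sign change of the source series (the Lorenz x
    coordinate switches sign when the trajectory jumps between wings). A
    switch counts as "preceded" if |v_r| exceeds its ``quantile`` threshold
    anywhere in the ``pre_window`` samples before it. The observed
    preceded fraction is compared with the same fraction at uniformly
    random time points (add-one permutation p over ``n_permutations``
    draws).
    """
    if emb.V is None:
        raise ValueError("run svd_embedding first")
    if not 1 <= r <= emb.k:
        raise ValueError(f"forcing index r={r} outside [1, k={emb.k}]")
    x = np.asarray(series, dtype=float).ravel()
    v = emb.V[:, r - 1]
    n = v.size
    burst = np.abs(v) > np.quantile(np.abs(v), quantile)
    switches = np.flatnonzero(np.diff(np.sign(x[:n])) != 0) + 1
    switches = switches[switches >= pre_window]
    if switches.size < 50:
        raise ValueError(f"only {switches.size} lobe switches; need >= 50")

    def preceded_fraction(idx: np.ndarray) -> float:
        return float(np.mean([burst[i - pre_window : i].any() for i in idx]))

    observed = preceded_fraction(switches)
    rng = np.random.default_rng(seed)
    null = np.array(
        [
            preceded_fraction(rng.integers(pre_window, n, size=switches.size))
            for _ in range(n_permutations)
        ]
    )
    from .nulls import permutation_pvalue

    return {
        "n_switches": int(switches.size),
        "observed_fraction": observed,
        "null_fractions": null,
        "null_mean": float(null.mean()),
        "p_value": permutation_pvalue(observed, null),
    }


def sweep_forcing_accuracy(
    emb: DelayEmbedding,
    r_values: range | list[int] = range(4, 23),
    train_span: tuple[int, int] | None = None,
    dims: list[int] | None = None,
) -> dict[int, np.ndarray]:
    """Fit + simulate with true future forcing for each forcing index r.

    Returns {r: per-dimension 1/MSE on the held-out span}. Mirrors the
    forcing-index sweep used to locate the most predictive system size.
    """
    if emb.V is None:
        raise ValueError("run svd_embedding first")
    span = train_span or (0, min(TRAIN_HOURS_SIX_MONTHS, emb.V.shape[0] // 2))
    out: dict[int, np.ndarray] = {}
    for r in r_values:
        if r > emb.k:
            raise ValueError(f"r={r} exceeds truncation k={emb.k}")
        sys = fit_havok(emb.V, r, span)
        sim, truth = predict_test_span(sys, emb.V)
        d = dims or list(range(1, min(3, r - 1) + 1))
        out[r] = prediction_accuracy(sim.V_pred, truth, d)
    return out
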