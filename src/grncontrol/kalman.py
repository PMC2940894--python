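"""Optimal estimation of an upstream regulator from noisy downstream measurements.

In simple regulation X->Y, protein y integrates the activity of its
regulator x. Euler discretization of the linear rate law with step ``h``
gives the recursion ``y_{k+1} = (1 - hD) y_k + hF x_k`` — a known linear map
from the x history to the y series. Estimation proceeds in three stages of
increasing realism:

* batch (weighted) least squares recovers a noise-free x history from noisy
  y measurements, ``x_hat = (H' S^-1 H)^-1 H' S^-1 y``;
* recursive least squares ingests measurements one at a time with a gain
  matrix and covariance recursion, reproducing the batch answer exactly;
* the discrete-time Kalman filter alternates mean/covariance propagation
  through the dynamics (process noise Q for the intrinsic fluctuation of x)
  with recursive-least-squares measurement updates (covariance Sigma for the
  extrinsic noise on y), yielding the linear-Gaussian optimal estimate of a
  fluctuating x.

Covariance measurement updates use the Joseph stabilized form, which keeps
the matrices symmetric positive semi-definite over long runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "DiscretizedSystem",
    "MeasurementModel",
    "NoiseModel",
    "FilterState",
    "KalmanFilterResult",
    "build_measurement_model",
    "least_squares_estimate",
    "recursive_ls_update",
    "propagate",
    "kalman_filter",
    "naive_inversion_estimate",
]


@dataclass(frozen=True)
class DiscretizedSystem:
    """Euler-discretized simple regulation ``y_{k+1} = (1-hD) y_k + hF x_k``.

    Basal production and the initial y are taken as zero. Requires
    ``0 < 1 - hD`` for a stable discretization.
    """

    F: float
    D: float
    h: float = 1.0
    n_steps: int = 1000

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"step size h must be > 0, got {self.h}")
        if self.F <= 0 or self.D <= 0:
            raise ValueError("F and D must be > 0")
        if self.h * self.D >= 1:
            raise ValueError(
                f"hD = {self.h * self.D} >= 1: Euler discretization unstable; reduce h"
            )
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def decay(self) -> float:
        return 1.0 - self.h * self.D


@dataclass(frozen=True)
class MeasurementModel:
    """Linear map ``y = H x`` from the x history to the y series, plus noise covariance."""

    H: np.ndarray
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        S = np.asarray(self.Sigma, dtype=float)
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "Sigma", S)
        if S.shape != (H.shape[0], H.shape[0]):
            raise ValueError("Sigma must be square with one row per measurement")
        if not np.allclose(S, S.T):
            raise ValueError("Sigma must be symmetric")
        if np.any(np.linalg.eigvalsh(S) < -1e-12):
            raise ValueError("Sigma must be positive semi-definite")


@dataclass(frozen=True)
class NoiseModel:
    """Standard deviations of the intrinsic state noise on x and extrinsic noise on y."""

    x_sd: float = 10.0
    y_sd: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x_sd < 0 or self.y_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class FilterState:
    """Prior/posterior estimate and estimation-error covariance of one recursion step."""

    x_prior: np.ndarray
    x_post: np.ndarray
    P_prior: np.ndarray
    P_post: np.ndarray
    K: Optional[np.ndarray] = None

    @classmethod
    def initial(cls, x0, P0) -> "FilterState":
        x0 = np.atleast_1d(np.asarray(x0, dtype=float))
        P0 = np.atleast_2d(np.asarray(P0, dtype=float))
        return cls(x_prior=x0, x_post=x0, P_prior=P0, P_post=P0)


def build_measurement_model(sys: DiscretizedSystem, y_noise_sd: float) -> MeasurementModel:
    """Unroll the Euler recursion into ``y = H x``.

    With ``y_1 = 0``, the measurement ``y_{k+1}`` collects the geometrically
    discounted x history: ``H[k, j] = hF (1-hD)^{k-j}`` for ``j <= k``
    (lower triangular, full rank). For constant x the row sums converge to
    ``F/D``, the continuous steady-state gain.
    """
    n = sys.n_steps
    k = np.arange(n)
    expo = k[:, None] - k[None, :]
    H = np.where(expo >= 0, sys.h * sys.F * sys.decay ** np.clip(expo, 0, None), 0.0)
    Sigma = (y_noise_sd**2) * np.eye(n)
    return MeasurementModel(H=H, Sigma=Sigma)


def least_squares_estimate(
    y: np.ndarray,
    mm: MeasurementModel,
    prior: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> np.ndarray:
    """(Weighted) least-squares estimate of the x history from noisy y.

    Solves ``x_hat = (H' S^-1 H)^-1 H' S^-1 y``; with ``Sigma = sigma^2 I``
    this is ordinary least squares. An optional Gaussian ``prior`` (mean,
    covariance) turns it into the regularized solution that the recursive
    estimator reproduces exactly.
    """
    y = np.asarray(y, dtype=float)
    H, S = mm.H, mm.Sigma
    if y.shape[0] != H.shape[0]:
        raise ValueError(f"y has {y.shape[0]} entries but H has {H.shape[0]} rows")
    if np.linalg.matrix_rank(H) < H.shape[1]:
        raise ValueError("H is rank-deficient: the x history is not identifiable")
    Sinv_H = np.linalg.solve(S, H)
    info = H.T @ Sinv_H
    rhs = Sinv_H.T @ y
    if prior is not None:
        x0, P0 = prior
        P0inv = np.linalg.inv(np.atleast_2d(P0))
        info = info + P0inv
        rhs = rhs + P0inv @ np.atleast_1d(x0)
    return np.linalg.solve(info, rhs)


def recursive_ls_update(
    state: FilterState, y_new: float, H_new: np.ndarray, noise_var: float
) -> FilterState:
    """One recursive-least-squares measurement update.

    Gain ``K = P H' (H P H' + R)^-1``; estimate
    ``x <- x + K (y - H x)``; covariance via the Joseph form
    ``P <- (I - K H) P (I - K H)' + K R K'``. Processing the rows of a batch
    problem one-by-one reproduces the batch solution.
    """
    H_row = np.atleast_2d(np.asarray(H_new, dtype=float))
    P = state.P_post
    x = state.x_post
    innov_cov = H_row @ P @ H_row.T + np.atleast_2d(noise_var)
    if np.any(np.linalg.eigvalsh(innov_cov) <= 0):
        raise ValueError("innovation covariance is not positive definite")
    K = P @ H_row.T @ np.linalg.inv(innov_cov)
    resid = np.atleast_1d(y_new) - H_row @ x
    x_new = x + (K @ resid).ravel()
    IKH = np.eye(P.shape[0]) - K @ H_row
    P_new = IKH @ P @ IKH.T + K @ np.atleast_2d(noise_var) @ K.T
    P_new = 0.5 * (P_new + P_new.T)
    return FilterState(x_prior=x, x_post=x_new, P_prior=P, P_post=P_new, K=K)


def propagate(
    state: FilterState,
    transition: np.ndarray,
    input_term: np.ndarray | float = 0.0,
    Q: np.ndarray | float = 0.0,
) -> FilterState:
    """Time update: propagate mean and covariance through the linear dynamics.

    ``x <- Phi x + u`` and ``P <- Phi P Phi' + Q`` with known input ``u`` and
    process-noise covariance ``Q``.
    """
    Phi = np.atleast_2d(np.asarray(transition, dtype=float))
    u = np.broadcast_to(np.atleast_1d(np.asarray(input_term, dtype=float)), (Phi.shape[0],))
    Qm = np.asarray(Q, dtype=float)
    if Qm.ndim < 2:
        Qm = np.eye(Phi.shape[0]) * Qm
    x_new = Phi @ state.x_post + u
    P_new = Phi @ state.P_post @ Phi.T + Qm
    P_new = 0.5 * (P_new + P_new.T)
    return FilterState(x_prior=x_new, x_post=x_new, P_prior=P_new, P_post=P_new, K=None)


@dataclass(frozen=True)
class KalmanFilterResult:
    """Per-step Kalman estimates of the upstream regulator x.

    ``x_prior``/``x_post`` are the a-priori/a-posteriori estimates of x at
    each measurement time, ``P_prior``/``P_post`` the matching error
    variances (x component) and ``gain`` the x row of the Kalman gain.
    """

    x_prior: np.ndarray
    x_post: np.ndarray
    P_prior: np.ndarray
    P_post: np.ndarray
    gain: np.ndarray
    history: list[FilterState]

    @property
    def estimates(self) -> np.ndarray:
        return self.x_post

    def summary(self) -> dict[str, float]:
        return {
            "n_steps": int(self.x_post.size),
            "mean_estimate": float(np.mean(self.x_post)),
            "final_posterior_sd": float(np.sqrt(self.P_post[-1])),
        }


def kalman_filter(
    y: np.ndarray,
    sys: DiscretizedSystem,
    noise: NoiseModel,
    x0: float,
    P0: float,
    Q: Optional[float] = None,
) -> KalmanFilterResult:
    """Discrete-time Kalman filter estimating a fluctuating x from noisy y.

    The filter runs on the exact joint model of the measurement process:
    state ``(x_k, y_k)`` with transition ``[[1, 0], [hF, 1-hD]]`` (x carries
    the random-walk prior with process variance ``Q = x_sd**2``; the y row is
    the deterministic Euler recursion), and measurement ``y_k`` plus
    extrinsic noise of variance ``y_sd**2``. Each step performs a
    recursive-least-squares measurement update followed by a mean/covariance
    time update. ``x0`` and ``P0`` initialize the x estimate; ``y_1 = 0`` is
    known exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != sys.n_steps:
        raise ValueError(f"y must be a 1-D series of length n_steps={sys.n_steps}, got shape {y.shape}")
    q = noise.x_sd**2 if Q is None else float(Q)
    R = max(noise.y_sd**2, 1e-12)  # a zero-noise measurement still needs a PD innovation
    Phi = np.array([[1.0, 0.0], [sys.h * sys.F, sys.decay]])
    Qm = np.diag([q, 0.0])
    H_row = np.array([[0.0, 1.0]])
    state = FilterState.initial([x0, 0.0], np.diag([P0, 0.0]))

    n = y.size
    x_prior = np.empty(n)
    x_post = np.empty(n)
    P_prior = np.empty(n)
    P_post = np.empty(n)
    gain = np.empty(n)
    history: list[FilterState] = []
    for k in range(n):
        x_prior[k] = state.x_post[0]
        P_prior[k] = state.P_post[0, 0]
        state = recursive_ls_update(state, y[k], H_row, R)
        x_post[k] = state.x_post[0]
        P_post[k] = state.P_post[0, 0]
        gain[k] = state.K[0, 0]
        history.append(state)
        if k < n - 1:
            state = propagate(state, Phi, 0.0, Qm)
    return KalmanFilterResult(
        x_prior=x_prior, x_post=x_post, P_prior=P_prior, P_post=P_post, gain=gain, history=history
    )


def naive_inversion_estimate(y: np.ndarray, sys: DiscretizedSystem) -> np.ndarray:
    """Per-step inversion of the Euler recursion, ``(y_{k+1} - (1-hD) y_k) / (hF)``.

    The model-free baseline the filter is compared against: unbiased but
    amplifies the measurement noise by ``1/(hF)``.
    """
    y = np.asarray(y, dtype=float)
    return (y[1:] - sys.decay * y[:-1]) / (sys.h * sys.F)
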