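"""Linear (possibly time-varying) state-space models of gene networks.

A network of linearized genes is ``ds/dt = A(t) s + B u(t)`` where the state
``s`` collects protein concentrations, the diagonal of ``A`` carries the
negative degradation/dilution constants (shifted by autoregulation), the
off-diagonals the signed regulation strengths, and ``u`` the external drives
plus basal rates. Eigenvalues of ``A`` play the role of the transfer
function's poles: negative real parts mean stability, nonzero imaginary
parts oscillation. Simulation uses the forward Euler scheme
``s_{k+1} = s_k + h (A s_k + B u_k)``, the same discretization that
underlies the estimation pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .network import NetworkSpec

__all__ = [
    "StateSpaceModel",
    "EigenAnalysis",
    "Equilibrium",
    "SimulationResult",
    "DivergenceError",
    "from_network",
    "build_simple_regulation",
    "build_negative_feedback",
    "build_six_node",
    "eigen_analysis",
    "equilibrium",
    "simulate",
    "vector_field",
]

MatrixLike = Union[np.ndarray, Callable[[float], np.ndarray]]
VectorLike = Union[np.ndarray, Callable[[float], np.ndarray], float]


class DivergenceError(RuntimeError):
    """Euler integration produced non-finite values."""


@dataclass(frozen=True)
class StateSpaceModel:
    """``ds/dt = A(t) s + B u(t)`` with labelled states.

    ``A`` may be a constant matrix or a callable of time; ``u`` a constant
    vector or a callable of time.
    """

    A: MatrixLike
    B: np.ndarray
    u: VectorLike
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "labels", tuple(self.labels))
        A0 = self.A_at(0.0)
        if A0.shape[0] != A0.shape[1]:
            raise ValueError("A must be square")
        if B.shape[0] != A0.shape[0]:
            raise ValueError("B row count must equal the state dimension")
        if len(self.labels) != A0.shape[0]:
            raise ValueError("labels length must equal the state dimension")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def A_at(self, t: float) -> np.ndarray:
        A = self.A(t) if callable(self.A) else self.A
        return np.atleast_2d(np.asarray(A, dtype=float))

    def u_at(self, t: float) -> np.ndarray:
        u = self.u(t) if callable(self.u) else self.u
        return np.atleast_1d(np.asarray(u, dtype=float))

    def derivative(self, t: float, s: np.ndarray) -> np.ndarray:
        return self.A_at(t) @ np.asarray(s, dtype=float) + self.B @ self.u_at(t)

    @property
    def time_invariant(self) -> bool:
        return not (callable(self.A) or callable(self.u))


# -- builders --------------------------------------------------------------


def from_network(spec: NetworkSpec) -> StateSpaceModel:
    """State-space model of a NetworkSpec under its constant drives."""
    A, b = spec.state_matrices()
    return StateSpaceModel(A=A, B=np.eye(len(b)), u=b, labels=spec.node_names)


def build_simple_regulation(
    f: Union[float, Callable[[float], float]],
    d: Union[float, Callable[[float], float]],
    x: Union[float, Callable[[float], float]],
    basal: float = 0.0,
    label: str = "y",
) -> StateSpaceModel:
    """One-gene model ``dy/dt = -d(t) y + f(t) x(t) + F0``.

    ``f`` and ``d`` need not be time-invariant — the state-space form, unlike
    the transfer function, accommodates time-varying production and
    degradation.
    """
    f_t = f if callable(f) else (lambda t, _v=float(f): _v)
    d_t = d if callable(d) else (lambda t, _v=float(d): _v)
    x_t = x if callable(x) else (lambda t, _v=float(x): _v)
    time_varying = callable(f) or callable(d) or callable(x)
    if time_varying:
        A: MatrixLike = lambda t: np.array([[-d_t(t)]])
        u: VectorLike = lambda t: np.array([f_t(t) * x_t(t) + basal])
    else:
        A = np.array([[-d_t(0.0)]])
        u = np.array([f_t(0.0) * x_t(0.0) + basal])
    return StateSpaceModel(A=A, B=np.eye(1), u=u, labels=(label,))


def build_negative_feedback(
    d_y: float,
    d_z: float,
    f_yz: float,
    f_zy: float,
    drive: float,
    basal_y: float = 0.0,
    basal_z: float = 0.0,
) -> StateSpaceModel:
    """Two-gene negative feedback loop: X->Y->Z with Z repressing Y.

    ``dy/dt = drive - f_zy z - d_y y + F0y``;
    ``dz/dt = f_yz y - d_z z + F0z``. ``drive`` is the constant upstream
    input ``f_xy * x``.
    """
    for name, v in dict(d_y=d_y, d_z=d_z, f_yz=f_yz, f_zy=f_zy).items():
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    A = np.array([[-d_y, -f_zy], [f_yz, -d_z]])
    u = np.array([drive + basal_y, basal_z])
    return StateSpaceModel(A=A, B=np.eye(2), u=u, labels=("y", "z"))


SIX_NODE_LABELS = ("A", "B", "C", "D", "E", "F")
FFL_EDGES = (("A", "B"), ("A", "C"), ("B", "C"))


def build_six_node(spec: NetworkSpec, drive: float = None) -> StateSpaceModel:
    """Six-gene network driven by an external gene X acting on gene A.

    The spec must label its nodes A..F and contain the coherent type-1
    feedforward loop A->B, A->C, B->C (all activating), which delays C's
    expression relative to B's. ``drive`` overrides the spec's input on A.
    """
    if sorted(spec.node_names) != sorted(SIX_NODE_LABELS):
        raise ValueError(f"six-node wiring requires nodes {SIX_NODE_LABELS}, got {spec.node_names}")
    present = {(e.source, e.target) for e in spec.edges if e.sign == "activation"}
    missing = [e for e in FFL_EDGES if e not in present]
    if missing:
        raise ValueError(f"six-node wiring must embed the A,B,C feedforward loop; missing activating edges {missing}")
    model = from_network(spec)
    if drive is not None:
        u = np.asarray(model.u, dtype=float).copy()
        u[model.labels.index("A")] = drive + next(n.basal for n in spec.nodes if n.name == "A")
        model = StateSpaceModel(A=model.A, B=model.B, u=u, labels=model.labels)
    return model


# -- analysis --------------------------------------------------------------


@dataclass(frozen=True)
class EigenAnalysis:
    """Eigen-decomposition of the state matrix with stability/oscillation verdicts."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    stable: bool
    oscillatory: bool

    @property
    def verdict(self) -> str:
        kind = "underdamped oscillation" if self.oscillatory else "monotone response"
        return f"{kind}, {'stable' if self.stable else 'not stable'}"


def eigen_analysis(model: StateSpaceModel, at_time: float = 0.0, atol: float = 1e-12) -> EigenAnalysis:
    """Eigenvalues/vectors of ``A`` (snapshot at ``at_time`` if time-varying).

    Eigenvalues are the poles of the equivalent transfer function: all real
    parts negative means stable; any nonzero imaginary part means the
    response oscillates.
    """
    A = model.A_at(at_time)
    lam, phi = np.linalg.eig(A)
    order = np.lexsort((lam.imag, lam.real))
    lam, phi = lam[order], phi[:, order]
    return EigenAnalysis(
        eigenvalues=lam,
        eigenvectors=phi,
        stable=bool(np.all(lam.real < 0)),
        oscillatory=bool(np.any(np.abs(lam.imag) > atol)),
    )


@dataclass(frozen=True)
class Equilibrium:
    """Concentrations at which all time derivatives vanish."""

    concentrations: np.ndarray
    labels: tuple[str, ...]
    residual: float
    reachable_note: str = "all trajectories of a stable linear system converge here"

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.concentrations.tolist()))


def equilibrium(model: StateSpaceModel, at_time: float = 0.0, rtol: float = 1e-9) -> Equilibrium:
    """Solve ``A s + B u = 0`` for the equilibrium concentrations."""
    A = model.A_at(at_time)
    rhs = -(model.B @ model.u_at(at_time))
    try:
        s_eq = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("state matrix is singular: no unique equilibrium") from exc
    residual = float(np.linalg.norm(A @ s_eq - rhs))
    scale = max(1.0, float(np.linalg.norm(rhs)))
    if residual > rtol * scale:
        raise ValueError(f"equilibrium residual {residual} exceeds tolerance")
    return Equilibrium(concentrations=s_eq, labels=model.labels, residual=residual)


# -- simulation ------------------------------------------------------------


@dataclass(frozen=True)
class SimulationResult:
    """Euler-integrated trajectories, one column per gene."""

    t: np.ndarray
    states: np.ndarray
    labels: tuple[str, ...]
    went_negative: bool = False

    def __getitem__(self, label: str) -> np.ndarray:
        return self.states[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, columns=list(self.labels)).assign(time_min=self.t).set_index("time_min")


def simulate(
    model: StateSpaceModel,
    s0: Sequence[float],
    t_end: float,
    h: float = 0.1,
) -> SimulationResult:
    """Forward-Euler simulation ``s_{k+1} = s_k + h(A s_k + B u_k)``.

    Warns when ``h`` exceeds the Euler stability bound ``2/max|Re lambda|``
    for a constant ``A``. Transiently negative concentrations are reported
    as-is (with a flag) — clamping would break linearity.
    """
    if h <= 0:
        raise ValueError(f"step size must be > 0, got {h}")
    s0 = np.asarray(s0, dtype=float)
    if s0.shape != (model.n_states,):
        raise ValueError(f"s0 must have shape ({model.n_states},), got {s0.shape}")
    if not callable(model.A):
        lam = np.linalg.eigvals(model.A_at(0.0))
        maxmag = float(np.max(np.abs(lam.real))) if lam.size else 0.0
        if maxmag > 0 and h > 2.0 / maxmag:
            warnings.warn(
                f"Euler step h={h} exceeds the stability bound {2.0 / maxmag:.4g}; "
                "the simulation may diverge",
                RuntimeWarning,
                stacklevel=2,
            )
    n_steps = int(np.ceil(t_end / h))
    t = np.linspace(0.0, n_steps * h, n_steps + 1)
    states = np.empty((n_steps + 1, model.n_states))
    states[0] = s0
    s = s0.copy()
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n_steps):
            s = s + h * model.derivative(t[k], s)
            if not np.all(np.isfinite(s)):
                raise DivergenceError(f"non-finite state at step {k + 1} (t = {t[k + 1]:g})")
            states[k + 1] = s
    return SimulationResult(
        t=t, states=states, labels=model.labels, went_negative=bool(np.any(states < 0))
    )


def vector_field(
    model: StateSpaceModel,
    grid_x: Sequence[float],
    grid_y: Sequence[float],
    state_pair: tuple[str, str] | None = None,
    fixed: Optional[dict[str, float]] = None,
    at_time: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Phase-plane vector field ``(ds_i/dt, ds_j/dt)`` over a 2-D grid.

    Returns ``(X, Y, U, V)`` meshgrid arrays; the arrow at the equilibrium is
    zero and arrows along any trajectory are tangent to it. For models with
    more than two states the remaining states are held at ``fixed`` values.
    """
    grid_x = np.asarray(grid_x, dtype=float)
    grid_y = np.asarray(grid_y, dtype=float)
    if not (np.all(np.isfinite(grid_x)) and np.all(np.isfinite(grid_y))):
        raise ValueError("grid must be finite")
    if state_pair is None:
        if model.n_states != 2:
            raise ValueError("state_pair must be given for models with more than two states")
        state_pair = (model.labels[0], model.labels[1])
    i = model.labels.index(state_pair[0])
    j = model.labels.index(state_pair[1])
    base = np.zeros(model.n_states)
    for name, value in (fixed or {}).items():
        base[model.labels.index(name)] = value
    X, Y = np.meshgrid(grid_x, grid_y)
    U = np.empty_like(X)
    V = np.empty_like(Y)
    for r in range(X.shape[0]):
        for c in range(X.shape[1]):
            s = base.copy()
            s[i], s[j] = X[r, c], Y[r, c]
            ds = model.derivative(at_time, s)
            U[r, c], V[r, c] = ds[i], ds[j]
    return X, Y, U, V
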