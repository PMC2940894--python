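"""Transfer-function algebra for gene-network motifs.

A linearized gene (simple regulation) is the first-order block
``G(s) = 1/(s + D)``: production drives the gene, degradation/dilution ``D``
sets the pole. Networks of such blocks are reduced to a single rational
transfer function with four rules — cascade (product), parallel (sum),
feedback closure ``G/(1 ± G H)``, and autoregulation collapse, which folds a
self-loop of strength ``H`` into an effective degradation constant
``D' = D + H`` (negative autoregulation) or ``D'' = D - H`` (positive).

Stability is read off the poles: all in the open left half-plane → stable;
simple poles on the imaginary axis and none to the right → marginally stable
(sustained oscillation); anything in the right half-plane → unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np

from .network import NetworkSpec

__all__ = [
    "RationalTF",
    "AutoregulationResult",
    "SteadyStateErrorReport",
    "UnsupportedTopologyError",
    "DegenerateLoopError",
    "FinalValueTheoremError",
    "simple_regulation_tf",
    "cascade",
    "parallel",
    "feedback",
    "autoregulation_tf",
    "reduce_network",
    "poles",
    "zeros",
    "is_stable",
    "steady_state_error",
]

# A pole counts as "on the imaginary axis" if |Re| < AXIS_TOL * max(1, |Im|);
# needed because roots of s^2 + b (a = 0 exactly) come back with float fuzz.
AXIS_TOL = 1e-9

# Exact-common-root cancellation tolerance after feedback closure.
CANCEL_TOL = 1e-9


class UnsupportedTopologyError(ValueError):
    """The network cannot be reduced to a single input->output transfer function."""


class DegenerateLoopError(ZeroDivisionError):
    """Feedback closure cancelled the loop denominator to zero."""


class FinalValueTheoremError(ValueError):
    """Final value theorem applied to an unstable closed loop."""


def _trim(c: np.ndarray) -> np.ndarray:
    c = np.atleast_1d(np.asarray(c, dtype=float))
    nz = np.flatnonzero(np.abs(c) > 0)
    return c[nz[0]:] if nz.size else np.zeros(1)


@dataclass(frozen=True)
class RationalTF:
    """A real-rational transfer function ``num(s)/den(s)``.

    Coefficients are stored descending in degree with the denominator monic.
    """

    num: np.ndarray
    den: np.ndarray

    def __init__(self, num: Iterable[float], den: Iterable[float]):
        num = _trim(num)
        den = _trim(den)
        if np.allclose(den, 0):
            raise ValueError("denominator is identically zero")
        lead = den[0]
        object.__setattr__(self, "num", num / lead)
        object.__setattr__(self, "den", den / lead)

    # -- basic queries -----------------------------------------------------

    @property
    def order(self) -> int:
        return len(self.den) - 1

    def __call__(self, s):
        """Evaluate the frequency response at (complex) ``s``."""
        s = np.asarray(s, dtype=complex)
        return np.polyval(self.num, s) / np.polyval(self.den, s)

    def dc_gain(self) -> float:
        return float(np.real(self(0.0)))

    def poles(self) -> np.ndarray:
        return _sorted_roots(self.den)

    def zeros(self) -> np.ndarray:
        if len(self.num) < 2:
            return np.array([], dtype=complex)
        return _sorted_roots(self.num)

    def cancel(self, tol: float = CANCEL_TOL) -> "RationalTF":
        """Cancel exact common numerator/denominator roots (within ``tol``)."""
        if len(self.num) < 2 or len(self.den) < 2:
            return self
        z = list(np.roots(self.num))
        p = list(np.roots(self.den))
        gain = self.num[0]
        kept_z = []
        for zi in z:
            scale = max(1.0, abs(zi))
            match = next((j for j, pj in enumerate(p) if abs(zi - pj) < tol * scale), None)
            if match is None:
                kept_z.append(zi)
            else:
                p.pop(match)
        num = np.real(np.poly(kept_z)) * gain if kept_z else np.array([gain])
        den = np.real(np.poly(p)) if p else np.array([1.0])
        return RationalTF(num, den)

    def __repr__(self) -> str:
        return f"RationalTF(num={self.num.tolist()}, den={self.den.tolist()})"


def _sorted_roots(coeffs: np.ndarray) -> np.ndarray:
    r = np.roots(coeffs)
    order = np.lexsort((r.imag, r.real))
    return r[order]


# -- motif constructors and block-diagram rules ----------------------------


def simple_regulation_tf(D: float) -> RationalTF:
    """First-order block ``1/(s + D)`` of a simply regulated gene.

    The single pole at ``-D`` makes the degradation/dilution constant the
    sole determinant of the response speed.
    """
    if D <= 0:
        raise ValueError(f"degradation constant must be > 0, got {D}")
    return RationalTF([1.0], [1.0, D])


def constant_tf(k: float) -> RationalTF:
    return RationalTF([float(k)], [1.0])


def cascade(a: RationalTF, b: RationalTF) -> RationalTF:
    """Series connection: the product ``a(s) * b(s)``."""
    return RationalTF(np.polymul(a.num, b.num), np.polymul(a.den, b.den))


def parallel(a: RationalTF, b: RationalTF) -> RationalTF:
    """Parallel connection: the algebraic sum ``a(s) + b(s)``."""
    num = np.polyadd(np.polymul(a.num, b.den), np.polymul(b.num, a.den))
    return RationalTF(num, np.polymul(a.den, b.den))


class _Factored:
    """Rational gain in factored form ``gain * prod(s - z) / prod(s - p)``.

    Internal to the network reduction: keeping the factors explicit lets the
    elimination cancel structurally shared factors by pairwise matching
    instead of re-finding (possibly repeated, ill-conditioned) polynomial
    roots from summed coefficients.
    """

    __slots__ = ("gain", "zeros", "poles")
    MATCH_TOL = 1e-8

    def __init__(self, gain: float, zeros: list[complex] | None = None, poles: list[complex] | None = None):
        self.gain = float(gain)
        self.zeros = list(zeros or [])
        self.poles = list(poles or [])
        if self.gain == 0.0:
            self.zeros = []
        self._cancel_pairs()

    @staticmethod
    def _match(r: complex, pool: list[complex]) -> Optional[int]:
        for i, q in enumerate(pool):
            if abs(r - q) < _Factored.MATCH_TOL * max(1.0, abs(r)):
                return i
        return None

    def _cancel_pairs(self) -> None:
        remaining = []
        for z in self.zeros:
            j = self._match(z, self.poles)
            if j is None:
                remaining.append(z)
            else:
                self.poles.pop(j)
        self.zeros = remaining

    @property
    def is_zero(self) -> bool:
        return self.gain == 0.0

    def mul(self, other: "_Factored") -> "_Factored":
        return _Factored(self.gain * other.gain, self.zeros + other.zeros, self.poles + other.poles)

    def add(self, other: "_Factored") -> "_Factored":
        if self.is_zero:
            return other
        if other.is_zero:
            return self
        # factor out shared zeros and shared poles before adding coefficients
        a_z, b_z, shared_z = _split_shared(self.zeros, other.zeros)
        a_p, b_p, shared_p = _split_shared(self.poles, other.poles)
        bracket = np.polyadd(
            self.gain * np.poly(a_z + b_p) if (a_z or b_p) else np.array([self.gain]),
            other.gain * np.poly(b_z + a_p) if (b_z or a_p) else np.array([other.gain]),
        )
        bracket = _trim(np.real_if_close(bracket, tol=1e3))
        if np.allclose(bracket, 0):
            return _Factored(0.0)
        new_zeros = shared_z + list(np.roots(bracket))
        return _Factored(bracket[0], new_zeros, shared_p + a_p + b_p)

    def inverse_one_minus(self) -> "_Factored":
        """Return ``1 / (1 - self)`` — the self-loop/feedback closure factor."""
        p_poly = np.poly(self.poles) if self.poles else np.array([1.0])
        z_poly = self.gain * (np.poly(self.zeros) if self.zeros else np.array([1.0]))
        pad = len(p_poly) - len(z_poly)
        if pad < 0:
            raise DegenerateLoopError("improper loop gain")
        one_minus = np.polysub(p_poly, np.concatenate([np.zeros(pad), z_poly]))
        one_minus = _trim(np.real(one_minus))
        if np.allclose(one_minus, 0):
            raise DegenerateLoopError("unit-gain loop: closed-loop denominator vanished")
        return _Factored(1.0 / one_minus[0], self.poles, list(np.roots(one_minus)))

    def to_rational(self) -> RationalTF:
        num = self.gain * (np.real(np.poly(self.zeros)) if self.zeros else np.array([1.0]))
        den = np.real(np.poly(self.poles)) if self.poles else np.array([1.0])
        return RationalTF(num, den)


def _split_shared(a: list[complex], b: list[complex]) -> tuple[list[complex], list[complex], list[complex]]:
    """Split two factor lists into (a-only, b-only, shared), pairing within tolerance."""
    b_left = list(b)
    a_only, shared = [], []
    for r in a:
        j = _Factored._match(r, b_left)
        if j is None:
            a_only.append(r)
        else:
            shared.append(b_left.pop(j))
    return a_only, b_left, shared


def feedback(G: RationalTF, H: RationalTF, sign: Literal["negative", "positive"] = "negative") -> RationalTF:
    """Close a loop around ``G`` with feedback element ``H``.

    Negative feedback gives ``G / (1 + G H)``, positive ``G / (1 - G H)``.
    """
    if sign not in ("negative", "positive"):
        raise ValueError(f"sign must be 'negative' or 'positive', got {sign!r}")
    gh_num = np.polymul(G.num, H.num)
    cross = np.polymul(G.den, H.den)
    if sign == "negative":
        den = np.polyadd(cross, gh_num)
    else:
        den = np.polysub(cross, gh_num)
    den = _trim(den)
    if np.allclose(den, 0):
        raise DegenerateLoopError("closed-loop denominator cancelled to zero")
    return RationalTF(np.polymul(G.num, H.den), den).cancel()


@dataclass(frozen=True)
class AutoregulationResult:
    """Autoregulation collapsed to an effective first-order block."""

    tf: RationalTF
    effective_degradation: float
    stability: str


def autoregulation_tf(D: float, H: float, sign: Literal["negative", "positive"]) -> AutoregulationResult:
    """Collapse autoregulation of strength ``H`` on a gene with degradation ``D``.

    Negative autoregulation (NAR) yields ``1/(s + D + H)``: a faster, lower
    steady-state response. Positive autoregulation (PAR) yields
    ``1/(s + D - H)``: slower and higher, and unstable once ``H > D``.
    Instability is reported in the result, not raised.
    """
    if D <= 0 or H <= 0:
        raise ValueError("D and H must be > 0")
    eff = D + H if sign == "negative" else D - H
    tf = RationalTF([1.0], [1.0, eff])
    return AutoregulationResult(tf=tf, effective_degradation=eff, stability=is_stable(tf))


# -- whole-network reduction ----------------------------------------------


def reduce_network(spec: NetworkSpec) -> RationalTF:
    """Reduce a network to the transfer function from its input drive to its output node.

    The reduction is a sequence of the four block-diagram rules applied via
    node elimination: self-loops are closed first (autoregulation/feedback
    rule), then each intermediate gene is removed by splicing its incoming
    and outgoing branches (cascade rule), accumulating parallel branches by
    summation. Loops are thereby closed innermost-first as their interior
    nodes disappear.
    """
    names = spec.node_names
    if not names:
        raise UnsupportedTopologyError("network has no nodes")
    in_node = spec.input_node or (names[0] if len(names) == 1 else None)
    out_node = spec.output_node or (names[0] if len(names) == 1 else None)
    if in_node is None or out_node is None:
        raise UnsupportedTopologyError("input_node and output_node must be designated")

    # Signal-flow gains T[i][j]: contribution of gene j's concentration to
    # gene i's, after absorbing gene i's first-order block. "u" is the input.
    # Factored (gain, zeros, poles) form keeps repeated-factor cancellation exact.
    degr = {n.name: n.degradation for n in spec.nodes}
    T: dict[str, dict[str, _Factored]] = {i: {} for i in names}
    for e in spec.edges:
        gain = _Factored(e.signed_strength, [], [-degr[e.target]])
        prev = T[e.target].get(e.source, _Factored(0.0))
        T[e.target][e.source] = prev.add(gain)
    T[in_node]["u"] = _Factored(1.0, [], [-degr[in_node]])

    # collapse autoregulations first, then eliminate intermediates one by one
    for k in names:
        _eliminate_self_loop(T, k)
    for k in [n for n in names if n != out_node]:
        _eliminate_self_loop(T, k)
        incoming = T.pop(k)
        for i in list(T):
            g_ik = T[i].pop(k, None)
            if g_ik is None:
                continue
            for j, g_kj in incoming.items():
                prev = T[i].get(j, _Factored(0.0))
                T[i][j] = prev.add(g_ik.mul(g_kj))
    _eliminate_self_loop(T, out_node)
    result = T[out_node].get("u")
    if result is None or result.is_zero:
        raise UnsupportedTopologyError(f"no signal path from {in_node!r} to {out_node!r}")
    return result.to_rational()


def _eliminate_self_loop(T: dict[str, dict[str, _Factored]], k: str) -> None:
    """Close a self-loop at node ``k``: every incoming gain g becomes g/(1 - L)."""
    loop = T.get(k, {}).pop(k, None)
    if loop is None or loop.is_zero:
        return
    inv = loop.inverse_one_minus()
    for j, g in list(T[k].items()):
        T[k][j] = g.mul(inv)


# -- pole/zero and stability queries ---------------------------------------


def poles(tf: RationalTF) -> np.ndarray:
    """Denominator roots with multiplicity, sorted by real part ascending."""
    return tf.poles()


def zeros(tf: RationalTF) -> np.ndarray:
    """Numerator roots with multiplicity, sorted by real part ascending."""
    return tf.zeros()


def is_stable(tf: RationalTF) -> str:
    """Classify as ``'stable'``, ``'marginally_stable'`` or ``'unstable'``.

    Stable systems have no poles with positive real part; simple poles on
    the imaginary axis give sustained (undamped) oscillation and marginal
    stability; repeated axis poles or right-half-plane poles are unstable.
    """
    p = tf.poles()
    on_axis = np.abs(p.real) < AXIS_TOL * np.maximum(1.0, np.abs(p.imag))
    right = p.real > AXIS_TOL * np.maximum(1.0, np.abs(p.imag))
    if np.any(right & ~on_axis):
        return "unstable"
    axis_poles = p[on_axis]
    if axis_poles.size == 0:
        return "stable"
    # repeated imaginary-axis poles grow polynomially -> unstable
    for i, pi in enumerate(axis_poles):
        for pj in axis_poles[i + 1:]:
            if abs(pi - pj) < AXIS_TOL * max(1.0, abs(pi)):
                return "unstable"
    return "marginally_stable"


# -- steady-state error under basal production -----------------------------


@dataclass(frozen=True)
class SteadyStateErrorReport:
    """Final-value-theorem steady-state error of the two-gene negative feedback loop.

    ``e_ss_signal`` is the residual error due to the reference drive,
    ``e_ss_basal`` the component due to the downstream gene's basal rate;
    the latter shrinks as either loop strength grows.
    """

    e_ss_signal: float
    e_ss_basal: float

    @property
    def total(self) -> float:
        return self.e_ss_signal + self.e_ss_basal


def steady_state_error(
    F_YZ: float,
    F_ZY: float,
    D_Y: float,
    D_Z: float,
    F_0Z: float = 0.0,
    F_step: float = 1.0,
) -> SteadyStateErrorReport:
    """Steady-state error of the X->Y->Z / Z-|Y loop with basal Z production.

    The loop error ``e(t) = F_step - F_ZY * z(t)`` settles, by the final
    value theorem, to a signal component ``F_step / (1 + L(0))`` and a basal
    component ``-F_ZY * F_0Z / D_Z / (1 + L(0))`` where
    ``L(0) = F_YZ F_ZY / (D_Y D_Z)`` is the DC loop gain. Raising ``F_YZ``
    or ``F_ZY`` suppresses the basal component.
    """
    G_Y = simple_regulation_tf(D_Y)
    G_Z = simple_regulation_tf(D_Z)
    loop = cascade(cascade(G_Y, G_Z), constant_tf(F_YZ * F_ZY))
    closed = feedback(cascade(G_Y, constant_tf(F_YZ)), cascade(G_Z, constant_tf(F_ZY)), "negative")
    if is_stable(closed) != "stable":
        raise FinalValueTheoremError("closed loop is not asymptotically stable; final value theorem does not apply")
    L0 = loop.dc_gain()
    e_signal = F_step / (1.0 + L0)
    e_basal = -F_ZY * G_Z.dc_gain() * F_0Z / (1.0 + L0)
    return SteadyStateErrorReport(e_ss_signal=e_signal, e_ss_basal=e_basal)
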