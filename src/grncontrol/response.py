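"""Time-domain step responses and first/second-order performance specifications.

First-order (simple regulation, ``G(s) = 1/(s+D)``) step responses follow
``y(t) = (F X / D)(1 - e^{-D t})``; the textbook specifications are the time
constant ``1/D`` (63% crossing), rise time ``2.2/D`` (10%->90%) and settling
time ``4/D`` (2% band, engineering approximation; the exact value is
``-ln(0.02)/D = 3.912/D``).

Second-order systems ``gain/(s^2 + a s + b)`` are characterized by the
natural frequency ``omega_n = sqrt(b)`` (the frequency of the undamped
oscillation) and damping ratio ``zeta = a / (2 sqrt(b))``: overdamped
(zeta > 1), critically damped (zeta = 1), underdamped (0 < zeta < 1) and
undamped (zeta = 0, marginally stable with poles on the imaginary axis).
The module also analyzes the two-gene tunable oscillator (positive
autoregulation on the activator supplies the negative term that can cancel
the total damping) and tracks the dominant pole pair of higher-order
circuits such as the four-gene IRMA analog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import expm
from scipy.signal import tf2ss

from .tf import RationalTF, is_stable

__all__ = [
    "FirstOrderSpecs",
    "SecondOrderForm",
    "SecondOrderSpecs",
    "OscillatorReport",
    "first_order_step_response",
    "first_order_specs",
    "second_order_specs",
    "oscillator_analysis",
    "dominant_poles",
    "step_response_numeric",
]

SETTLING_FRACTION = 0.02
# |a| below this multiple of omega_n counts as undamped ("close to zero")
UNDAMPED_RTOL = 1e-6


@dataclass(frozen=True)
class FirstOrderSpecs:
    """Step-response specifications of a first-order gene circuit (minutes)."""

    time_constant: float
    rise_time: float
    settling_time: float
    settling_time_exact: float

    def __post_init__(self) -> None:
        if not self.rise_time < self.settling_time:
            raise ValueError("rise_time must be smaller than settling_time")


def first_order_step_response(F: float, X: float, D: float, t) -> np.ndarray:
    """Closed-form step response ``(FX/D)(1 - e^{-Dt})`` of simple regulation.

    ``F`` is the linear production constant (per minute), ``X`` the constant
    input concentration, ``D`` the degradation/dilution constant. Starts from
    zero and rises monotonically to the steady state ``FX/D``.
    """
    if D <= 0:
        raise ValueError(f"degradation constant must be > 0, got {D}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise ValueError("t must be non-negative and strictly increasing")
    return (F * X / D) * (1.0 - np.exp(-D * t))


def first_order_specs(D: float) -> FirstOrderSpecs:
    """Time constant ``1/D``, rise time ``2.2/D``, settling time ``4/D``.

    ``settling_time`` is the engineering approximation; ``settling_time_exact``
    is the measured 2%-band entry ``-ln(0.02)/D``.
    """
    if D <= 0:
        raise ValueError(f"degradation constant must be > 0, got {D}")
    return FirstOrderSpecs(
        time_constant=1.0 / D,
        rise_time=2.2 / D,
        settling_time=4.0 / D,
        settling_time_exact=-np.log(SETTLING_FRACTION) / D,
    )


@dataclass(frozen=True)
class SecondOrderForm:
    """Second-order transfer function ``gain / (s^2 + a s + b)``.

    For the two-gene negative feedback loop, ``a = D_Y + D_Z`` and
    ``b = D_Y D_Z + F_YZ F_ZY``.
    """

    gain: float
    a: float
    b: float

    @classmethod
    def from_negative_feedback(cls, F_YZ: float, F_ZY: float, D_Y: float, D_Z: float) -> "SecondOrderForm":
        return cls(gain=F_YZ, a=D_Y + D_Z, b=D_Y * D_Z + F_YZ * F_ZY)

    def as_tf(self) -> RationalTF:
        return RationalTF([self.gain], [1.0, self.a, self.b])


@dataclass(frozen=True)
class SecondOrderSpecs:
    natural_frequency: float
    damping_ratio: float
    damped_frequency: Optional[float]
    damping_class: str
    peak_time: Optional[float] = None
    percent_overshoot: Optional[float] = None
    settling_time: Optional[float] = None


def second_order_specs(form: SecondOrderForm, undamped_rtol: float = UNDAMPED_RTOL) -> SecondOrderSpecs:
    """Natural frequency, damping ratio and damping class of a second-order form.

    Underdamped systems additionally get peak time ``pi/omega_d``, percent
    overshoot ``100 exp(-zeta pi / sqrt(1-zeta^2))`` and settling time
    ``4/(zeta omega_n)`` (standard second-order relations).
    """
    if form.b <= 0:
        raise ValueError(
            f"constant coefficient b must be > 0 for oscillatory structure, got {form.b}"
        )
    wn = float(np.sqrt(form.b))
    zeta = form.a / (2.0 * wn)
    if abs(zeta) < undamped_rtol:
        return SecondOrderSpecs(wn, 0.0, wn, "undamped")
    if zeta < 0:
        return SecondOrderSpecs(wn, zeta, wn * np.sqrt(1 - zeta**2) if zeta > -1 else None, "unstable")
    if abs(zeta - 1.0) < 1e-9:
        return SecondOrderSpecs(wn, 1.0, 0.0, "critically_damped")
    if zeta > 1:
        return SecondOrderSpecs(wn, zeta, None, "overdamped")
    wd = wn * float(np.sqrt(1.0 - zeta**2))
    return SecondOrderSpecs(
        natural_frequency=wn,
        damping_ratio=zeta,
        damped_frequency=wd,
        damping_class="underdamped",
        peak_time=np.pi / wd,
        percent_overshoot=100.0 * float(np.exp(-zeta * np.pi / np.sqrt(1.0 - zeta**2))),
        settling_time=4.0 / (zeta * wn),
    )


@dataclass(frozen=True)
class OscillatorReport:
    """Tuning analysis of the two-gene oscillator (positive autoregulation on
    gene 1, negative autoregulation on gene 2, mutual activation/repression).

    ``a = D1 + D2 - F1 + F3`` is the total damping: the positive
    autoregulation strength ``F1`` is its only negative term, which is why
    positive autoregulation is required for an undamped oscillation.
    ``b = (D1 - F1)(D2 + F3) + F2 F4`` sets the natural frequency; its
    negative terms ``-D2 F1`` and ``-F1 F3`` can destabilize the circuit.
    ``natural_frequency_nar_removed`` is the variant with the negative
    autoregulation deleted (``F3 = 0``), in which ``F4`` appears only in a
    positive term so the frequency becomes monotone in ``F4``.
    """

    a: float
    b: float
    natural_frequency: Optional[float]
    undamped: bool
    stability: str
    natural_frequency_nar_removed: Optional[float]
    f4_monotonic_when_nar_removed: bool

    def as_form(self, gain: float = 1.0) -> SecondOrderForm:
        return SecondOrderForm(gain=gain, a=self.a, b=self.b)


def oscillator_analysis(
    F1: float,
    F2: float,
    F3: float,
    F4: float,
    D1: float,
    D2: float,
    undamped_rtol: float = UNDAMPED_RTOL,
) -> OscillatorReport:
    """Analyze the tunable two-gene oscillator.

    Parameter roles: ``F1`` positive-autoregulation strength of gene 1,
    ``F2`` cross activation 1->2, ``F3`` negative-autoregulation strength of
    gene 2, ``F4`` cross repression 2->1; ``D1``, ``D2`` degradation
    constants. An undamped oscillation requires the damping ``a`` to vanish
    (``F1 = D1 + D2 + F3``) with ``b > 0`` so that the pole pair sits on the
    imaginary axis.
    """
    if min(F1, F2, F3, F4) < 0:
        raise ValueError("interaction strengths must be >= 0")
    if D1 <= 0 or D2 <= 0:
        raise ValueError("degradation constants must be > 0")
    a = D1 + D2 - F1 + F3
    b = (D1 - F1) * (D2 + F3) + F2 * F4
    wn = float(np.sqrt(b)) if b > 0 else None
    undamped = bool(b > 0 and abs(a) < undamped_rtol * np.sqrt(b))
    tf = RationalTF([1.0], [1.0, a, b])
    b_nar_removed = (D1 - F1) * D2 + F2 * F4
    return OscillatorReport(
        a=a,
        b=b,
        natural_frequency=wn,
        undamped=undamped,
        stability=is_stable(tf),
        natural_frequency_nar_removed=float(np.sqrt(b_nar_removed)) if b_nar_removed > 0 else None,
        f4_monotonic_when_nar_removed=F2 > 0,
    )


def dominant_poles(tf: RationalTF) -> np.ndarray:
    """The two slowest-decaying poles (greatest real part).

    These govern the long-time behavior; as interaction strengths grow they
    can cross the imaginary axis, at which point the circuit exhibits an
    undamped oscillation.
    """
    if tf.order < 2:
        raise ValueError(f"need a system of order >= 2, got order {tf.order}")
    p = tf.poles()  # sorted by real part ascending
    return p[-2:]


def step_response_numeric(tf: RationalTF, t) -> np.ndarray:
    """Unit-step response of a proper rational transfer function on a time grid.

    The transfer function is converted to controllable-canonical state-space
    and stepped with an exact zero-order-hold discretization (matrix
    exponential per grid interval), which reproduces the first-order closed
    form to float precision and conserves undamped oscillation amplitude.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t must be a 1-D increasing grid starting at 0")
    if len(tf.num) > len(tf.den):
        raise ValueError("transfer function must be proper (deg num <= deg den)")
    A, B, C, Dmat = tf2ss(tf.num, tf.den)
    n = A.shape[0]
    x = np.zeros(n)
    y = np.empty(t.size)
    y[0] = float(Dmat.ravel()[0]) if Dmat.size else 0.0
    # exact ZOH step: [x; u] propagates through exp([[A, B], [0, 0]] dt)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A
    aug[:n, n] = B.ravel()
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for k in range(1, t.size):
        dt = t[k] - t[k - 1]
        key = round(dt, 15)
        if key not in cache:
            M = expm(aug * dt)
            cache[key] = (M[:n, :n], M[:n, n])
        Ad, Bd = cache[key]
        x = Ad @ x + Bd
        y[k] = float((C @ x).ravel()[0] + Dmat.ravel()[0])
    return y
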