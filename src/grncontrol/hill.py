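"""Hill-function production kinetics and their two-section piecewise linearization.

Transcription-factor controlled protein production is modelled with Hill
functions: an activator ``x*`` drives production of a target protein at rate

    F(x*) = F0 + Fmax * x*^n / (K^n + x*^n)          (activation)
    F(x*) = F0 + Fmax * K^o / (K^o + x*^o)           (repression)

where ``F0`` is the basal promoter rate, ``Fmax`` the saturating rate, ``K``
the half-maximal concentration and ``n``/``o`` the Hill coefficient.

The linearization replaces the activation curve by a line through the origin
and the point ``(2K, Fmax)`` — i.e. slope ``F2 = Fmax / (2K)`` — clamped at
``Fmax`` for ``x* >= 2K``. Repression mirrors this: a line of slope ``-F2``
starting from ``Fmax`` at ``x* = 0``, clamped at zero for ``x* >= 2K``.
Signal-dependent transcription-factor activation enters as a scaling factor
in [0, 1] multiplying the total TF concentration.

Units throughout: concentrations in molecules/cell, rates per minute
(documented convention, not enforced).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np

__all__ = [
    "HillActivation",
    "HillRepression",
    "SignalScaling",
    "LinearizedRegulation",
    "hill_production_rate",
    "signal_scaling_factor",
    "linearize",
    "linearized_rate",
]


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class HillActivation:
    """Hill activation of a promoter by an active transcription factor.

    Parameters
    ----------
    f_max : float
        Maximal production rate (concentration/time), reached as x* >> K.
    K : float
        Concentration of x* at half-maximal production.
    coef : float
        Hill coefficient (steepness), >= 1.
    basal : float
        Basal promoter production rate F0 (concentration/time).
    """

    f_max: float
    K: float
    coef: float = 1.0
    basal: float = 0.0

    def __post_init__(self) -> None:
        _check_positive(f_max=self.f_max, K=self.K)
        if self.coef < 1:
            raise ValueError(f"coef must be >= 1, got {self.coef}")
        if self.basal < 0:
            raise ValueError(f"basal must be >= 0, got {self.basal}")


@dataclass(frozen=True)
class HillRepression:
    """Hill repression of a promoter: maximal rate ``f_max`` at zero repressor."""

    f_max: float
    K: float
    coef: float = 1.0
    basal: float = 0.0

    __post_init__ = HillActivation.__post_init__


@dataclass(frozen=True)
class SignalScaling:
    """Signal-to-active-TF scaling factor, a Hill curve in the signal s_x.

    ``mode='activator'``: the factor is 0 at zero signal and approaches 1 at
    saturating signal. ``mode='repressor'``: the mirror image (1 at zero
    signal, 0 at saturation). Multiplying the total TF concentration by this
    factor gives the active-TF concentration.
    """

    K1: float
    coef: float = 1.0
    mode: Literal["activator", "repressor"] = "activator"

    def __post_init__(self) -> None:
        _check_positive(K1=self.K1)
        if self.coef < 1:
            raise ValueError(f"coef must be >= 1, got {self.coef}")
        if self.mode not in ("activator", "repressor"):
            raise ValueError(f"mode must be 'activator' or 'repressor', got {self.mode!r}")


@dataclass(frozen=True)
class LinearizedRegulation:
    """Two-section linear approximation of a Hill regulation.

    ``slope = saturation_rate / threshold`` with ``threshold = 2K``; the rate
    law is ``basal + slope*x*`` below the threshold and
    ``basal + saturation_rate`` above it (activation), mirrored for
    repression.
    """

    slope: float
    saturation_rate: float
    threshold: float
    basal: float = 0.0
    repression: bool = False

    def __post_init__(self) -> None:
        _check_positive(saturation_rate=self.saturation_rate, threshold=self.threshold)
        if not np.isclose(self.slope, self.saturation_rate / self.threshold, rtol=1e-12):
            raise ValueError(
                "slope must equal saturation_rate / threshold "
                f"({self.saturation_rate / self.threshold}), got {self.slope}"
            )


Regulation = Union[HillActivation, HillRepression]


def hill_production_rate(x_star, reg: Regulation):
    """Production rate at active-TF concentration ``x_star``.

    Returns ``basal + Hill term``; the result is bounded in
    ``[basal, basal + f_max]``. Accepts scalars or arrays.
    """
    x = np.asarray(x_star, dtype=float)
    if np.any(x < 0):
        raise ValueError("x_star must be non-negative")
    xn = x**reg.coef
    Kn = reg.K**reg.coef
    if isinstance(reg, HillRepression):
        hill = reg.f_max * Kn / (Kn + xn)
    elif isinstance(reg, HillActivation):
        hill = reg.f_max * xn / (Kn + xn)
    else:
        raise TypeError(f"unsupported regulation type: {type(reg).__name__}")
    out = reg.basal + hill
    return out.item() if np.isscalar(x_star) else out


def signal_scaling_factor(s_x, sc: SignalScaling):
    """Fraction of transcription factor in active form at signal level ``s_x``.

    Always in [0, 1]: a Hill curve rising from 0 (activating signal) or
    falling from 1 (repressing signal).
    """
    s = np.asarray(s_x, dtype=float)
    if np.any(s < 0):
        raise ValueError("s_x must be non-negative")
    sn = s**sc.coef
    Kn = sc.K1**sc.coef
    frac = sn / (Kn + sn) if sc.mode == "activator" else Kn / (Kn + sn)
    return frac.item() if np.isscalar(s_x) else frac


def linearize(reg: Regulation) -> LinearizedRegulation:
    """Two-section piecewise linearization of a Hill regulation.

    The line passes through the origin and ``(2K, f_max)``, so
    ``slope = f_max / (2K)`` and the clamping threshold is ``2K``. The same
    slope magnitude is used for repression, descending from ``f_max``.
    """
    threshold = 2.0 * reg.K
    return LinearizedRegulation(
        slope=reg.f_max / threshold,
        saturation_rate=reg.f_max,
        threshold=threshold,
        basal=reg.basal,
        repression=isinstance(reg, HillRepression),
    )


def linearized_rate(x_star, lin: LinearizedRegulation, clamp: bool = True):
    """Piecewise-linear production rate at active-TF concentration ``x_star``.

    Activation: ``basal + slope*x*`` below the threshold, ``basal + Fmax``
    at and above it. Repression: ``basal + Fmax - slope*x*`` below the
    threshold, ``basal`` above it. With ``clamp=False`` the unclamped line is
    used everywhere (the regime of interest is x* below the threshold, where
    the two agree; repression is floored at ``basal`` even unclamped since a
    negative production rate is unphysical).
    """
    x = np.asarray(x_star, dtype=float)
    if np.any(x < 0):
        raise ValueError("x_star must be non-negative")
    if lin.repression:
        # floored at zero in both modes: negative production is unphysical
        rate = np.maximum(lin.saturation_rate - lin.slope * x, 0.0)
    else:
        line = lin.slope * x
        rate = np.minimum(line, lin.saturation_rate) if clamp else line
    out = lin.basal + rate
    return out.item() if np.isscalar(x_star) else out
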