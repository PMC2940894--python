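"""Synthetic-data generators and the registry of case-study networks.

Every analysis in the package is exercised on parameter sets from the
simulation conventions (degradation/dilution ``D = 0.01/min``, production
constants ``F`` in 0.01-0.1/min, inputs of 100-1000 molecules/cell) or on
wirings reconstructed from the case studies: autoregulation comparisons,
the two-gene negative feedback loop, the tunable oscillator, basal-rate
steady-state error, the four-gene IRMA analog, interconnected feedforward
loops, the Kalman estimation scenario and the six-gene network. Each
registered case study carries machine-checkable predicates encoding its
expected qualitative behavior; network wirings and parameter values live in
JSON files under ``grncontrol/data`` and are user-overridable.

The noise generators emulate constant-mean gene expression with Gaussian
zero-mean white intrinsic/extrinsic noise; they do not model bursty
transcription, cell division or correlated extrinsic fluctuations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional

import numpy as np

from . import response, statespace, tf
from .kalman import DiscretizedSystem, kalman_filter, NoiseModel
from .network import NetworkSpec
from .statespace import simulate

__all__ = [
    "CaseStudy",
    "CASE_STUDY_NAMES",
    "generate_noisy_x",
    "generate_y_from_x",
    "case_study",
    "load_fixture_network",
    "half_rise_time",
    "is_pulse",
    "scale_irma_interactions",
    "IRMA_SCALED_EDGES",
]

CASE_STUDY_NAMES = (
    "nar_par",
    "negative_feedback",
    "oscillator",
    "basal_error",
    "irma4",
    "ffl_cascade",
    "kalman_demo",
    "six_node",
)

# Edges of the IRMA analog whose common scaling drives the dominant poles
# across the imaginary axis.
IRMA_SCALED_EDGES = (("CBF1", "GAL4"), ("SWI5", "SWI5"), ("SWI5", "ASH1"), ("ASH1", "CBF1"))

PULSE_RATIO = 1.2  # a trajectory is a pulse if max > ratio * final value


# -- noise generators ------------------------------------------------------


def generate_noisy_x(n: int, mean: float = 200.0, sd: float = 10.0, seed: int = 0) -> np.ndarray:
    """Constant-mean regulator series with Gaussian zero-mean white noise.

    Emulates a protein held at ``mean`` molecules/cell whose intrinsic and
    extrinsic fluctuations combine into i.i.d. Gaussian noise of standard
    deviation ``sd``. Reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    return mean + sd * rng.standard_normal(n)


def generate_y_from_x(
    x: np.ndarray,
    sys: DiscretizedSystem,
    extrinsic_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Downstream protein series from the Euler recursion, plus extrinsic noise.

    ``y_1 = 0`` and ``y_{k+1} = (1-hD) y_k + hF x_k``; the recursion
    low-pass filters the fluctuations of x, so even the noise-free output
    fluctuates less than the scaled input. Gaussian extrinsic measurement
    noise of standard deviation ``extrinsic_sd`` is then added, drawn from a
    stream independent of the one used for x at the same seed.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    n = x.size
    y = np.zeros(n)
    for k in range(1, n):
        y[k] = sys.decay * y[k - 1] + sys.h * sys.F * x[k - 1]
    if extrinsic_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
        y = y + extrinsic_sd * rng.standard_normal(n)
    return y


# -- trajectory predicates -------------------------------------------------


def half_rise_time(t: np.ndarray, traj: np.ndarray) -> float:
    """First time the trajectory crosses half of its final value."""
    final = traj[-1]
    if final <= 0:
        raise ValueError("trajectory must settle at a positive value")
    above = np.flatnonzero(traj >= 0.5 * final)
    if above.size == 0:
        raise ValueError("trajectory never reaches half of its final value")
    return float(t[above[0]])


def is_pulse(traj: np.ndarray, ratio: float = PULSE_RATIO) -> bool:
    """A pulse overshoots: its maximum exceeds ``ratio`` times its final value."""
    return bool(np.max(traj) > ratio * traj[-1])


# -- registry --------------------------------------------------------------


def _load_json(name: str) -> dict:
    text = resources.files("grncontrol.data").joinpath(f"{name}.json").read_text()
    return json.loads(text)


def load_fixture_network(name: str) -> NetworkSpec:
    """Load one of the shipped NetworkSpec fixture files by name."""
    return NetworkSpec.model_validate(_load_json(name))


@dataclass(frozen=True)
class CaseStudy:
    """A named network/parameter set with machine-checkable behavior predicates."""

    name: str
    network: Optional[NetworkSpec]
    params: dict
    predicates: dict[str, Callable[["CaseStudy"], bool]] = field(default_factory=dict)

    def check(self) -> dict[str, bool]:
        """Evaluate every predicate; all must hold under the default parameters."""
        return {desc: bool(fn(self)) for desc, fn in self.predicates.items()}


def scale_irma_interactions(spec: NetworkSpec, factor: float) -> NetworkSpec:
    """Scale the oscillation-driving IRMA interaction strengths by a common factor."""
    data = spec.model_dump()
    for e in data["edges"]:
        if (e["source"], e["target"]) in IRMA_SCALED_EDGES:
            e["strength"] *= factor
    return NetworkSpec.model_validate(data)


def _63_time(t: np.ndarray, traj: np.ndarray) -> float:
    target = 0.632 * traj[-1]
    return float(t[np.flatnonzero(traj >= target)[0]])


def _nar_par_predicates() -> dict[str, Callable[[CaseStudy], bool]]:
    def responses(cs: CaseStudy):
        p = cs.params
        t = np.linspace(0.0, 1200.0, 2401)
        drive = p["F"] * p["X"]
        out = {}
        for label, eff in (("SR", p["D"]), ("NAR", p["D"] + p["H"]), ("PAR", p["D"] - p["H"])):
            out[label] = (t, drive / eff * (1 - np.exp(-eff * t)))
        return out

    def nar_faster_lower(cs: CaseStudy) -> bool:
        r = responses(cs)
        return (
            _63_time(*r["NAR"]) < _63_time(*r["SR"])
            and r["NAR"][1][-1] < r["SR"][1][-1]
        )

    def par_slower_higher(cs: CaseStudy) -> bool:
        r = responses(cs)
        return (
            _63_time(*r["PAR"]) > _63_time(*r["SR"])
            and r["PAR"][1][-1] > r["SR"][1][-1]
        )

    def strong_par_unstable(cs: CaseStudy) -> bool:
        p = cs.params
        res = tf.autoregulation_tf(p["D"], p["H_unstable"], "positive")
        return res.stability == "unstable"

    return {
        "NAR responds faster and settles lower than simple regulation": nar_faster_lower,
        "PAR responds slower and settles higher than simple regulation": par_slower_higher,
        "PAR with H > D is unstable": strong_par_unstable,
    }


def _negative_feedback_predicates() -> dict[str, Callable[[CaseStudy], bool]]:
    def equilibrium_200_800(cs: CaseStudy) -> bool:
        model = statespace.from_network(cs.network)
        eq = statespace.equilibrium(model)
        return np.allclose(eq.concentrations, [200.0, 800.0], rtol=1e-9)

    def underdamped_stable(cs: CaseStudy) -> bool:
        ana = statespace.eigen_analysis(statespace.from_network(cs.network))
        return ana.stable and ana.oscillatory

    def converges_from_400_400(cs: CaseStudy) -> bool:
        model = statespace.from_network(cs.network)
        res = simulate(model, [400.0, 400.0], t_end=1500.0, h=0.1)
        return bool(np.all(np.abs(res.states[-1] - [200.0, 800.0]) <= 0.005 * np.array([200.0, 800.0])))

    return {
        "equilibrium at (200, 800)": equilibrium_200_800,
        "eigenvalues predict underdamped, stable response": underdamped_stable,
        "trajectory from (400, 400) converges to the equilibrium": converges_from_400_400,
    }


def _oscillator_params(spec: NetworkSpec) -> dict[str, float]:
    strengths = {(e.source, e.target): e.strength for e in spec.edges}
    degr = {n.name: n.degradation for n in spec.nodes}
    return {
        "F1": strengths[("araC", "araC")],
        "F2": strengths[("araC", "lacI")],
        "F3": strengths[("lacI", "lacI")],
        "F4": strengths[("lacI", "araC")],
        "D1": degr["araC"],
        "D2": degr["lacI"],
    }


def _oscillator_predicates() -> dict[str, Callable[[CaseStudy], bool]]:
    def undamped_and_marginal(cs: CaseStudy) -> bool:
        rep = response.oscillator_analysis(**_oscillator_params(cs.network))
        return rep.undamped and rep.stability == "marginally_stable" and rep.b > 0

    def reduction_agrees(cs: CaseStudy) -> bool:
        rep = response.oscillator_analysis(**_oscillator_params(cs.network))
        G = tf.reduce_network(cs.network)
        return np.allclose(np.sort_complex(G.poles()), np.sort_complex(np.roots([1.0, rep.a, rep.b])), atol=1e-9)

    return {
        "default tuning is undamped and marginally stable": undamped_and_marginal,
        "block-diagram reduction reproduces the predicted pole pair": reduction_agrees,
    }


def _basal_error_predicates() -> dict[str, Callable[[CaseStudy], bool]]:
    def doubling_f_yz_shrinks_basal_error(cs: CaseStudy) -> bool:
        p = cs.params
        base = tf.steady_state_error(p["F_YZ"], p["F_ZY"], p["D_Y"], p["D_Z"], p["F_0Z"], p["F_step"])
        doubled = tf.steady_state_error(2 * p["F_YZ"], p["F_ZY"], p["D_Y"], p["D_Z"], p["F_0Z"], p["F_step"])
        return abs(doubled.e_ss_basal) < abs(base.e_ss_basal)

    def zero_basal_zero_component(cs: CaseStudy) -> bool:
        p = cs.params
        rep = tf.steady_state_error(p["F_YZ"], p["F_ZY"], p["D_Y"], p["D_Z"], 0.0, p["F_step"])
        return rep.e_ss_basal == 0.0

    return {
        "doubling F_YZ shrinks the basal-rate error component": doubling_f_yz_shrinks_basal_error,
        "zero basal rate gives a zero basal error component": zero_basal_zero_component,
    }


def _irma_predicates() -> dict[str, Callable[[CaseStudy], bool]]:
    def nominal_stable(cs: CaseStudy) -> bool:
        return tf.is_stable(tf.reduce_network(cs.network)) == "stable"

    def scaling_crosses_monotonically(cs: CaseStudy) -> bool:
        reals = []
        for k in np.linspace(1.0, 10.0, 19):
            scaled = scale_irma_interactions(cs.network, k)
            A, _ = scaled.state_matrices()
            reals.append(np.max(np.linalg.eigvals(A).real))
        reals = np.array(reals)
        return bool(np.all(np.diff(reals) > 0) and reals[0] < 0 and reals[-1] > 0)

    return {
        "nominal system is stable": nominal_stable,
        "scaling the four interactions moves the dominant poles monotonically across the axis": scaling_crosses_monotonically,
    }


def _ffl_predicates() -> dict[str, Callable[[CaseStudy], bool]]:
    def _run(cs: CaseStudy):
        model = statespace.from_network(cs.network)
        return simulate(model, np.zeros(model.n_states), t_end=2000.0, h=0.5)

    def sequential_half_rise(cs: CaseStudy) -> bool:
        res = _run(cs)
        times = [half_rise_time(res.t, res[g]) for g in ("C1", "C2", "C3")]
        return times[0] < times[1] < times[2]

    def incoherent_outputs_pulse(cs: CaseStudy) -> bool:
        res = _run(cs)
        return is_pulse(res["C1"]) and is_pulse(res["C2"]) and not is_pulse(res["C3"])

    return {
        "half-rise order C1 < C2 < C3": sequential_half_rise,
        "incoherent-loop outputs C1 and C2 pulse; coherent output C3 does not": incoherent_outputs_pulse,
    }


def _kalman_predicates() -> dict[str, Callable[[CaseStudy], bool]]:
    def estimate_near_mean(cs: CaseStudy) -> bool:
        p = cs.params
        sys = DiscretizedSystem(F=p["F"], D=p["D"], h=p["h"], n_steps=int(p["n_steps"]))
        x = generate_noisy_x(sys.n_steps, p["x_mean"], p["x_sd"], seed=0)
        y = generate_y_from_x(x, sys, extrinsic_sd=p["y_sd"], seed=0)
        res = kalman_filter(y, sys, NoiseModel(p["x_sd"], p["y_sd"], seed=0), x0=p["x0"], P0=p["P0"])
        burn = sys.n_steps // 10
        return abs(np.mean(res.x_post[burn:]) - p["x_mean"]) < 0.05 * p["x_mean"]

    return {"Kalman estimate of x hovers at the true mean": estimate_near_mean}


def _six_node_predicates() -> dict[str, Callable[[CaseStudy], bool]]:
    def c_delayed_vs_b(cs: CaseStudy) -> bool:
        model = statespace.build_six_node(cs.network)
        res = simulate(model, np.zeros(model.n_states), t_end=2000.0, h=0.5)
        return half_rise_time(res.t, res["C"]) > half_rise_time(res.t, res["B"])

    return {"gene C expression is delayed relative to gene B": c_delayed_vs_b}


_REGISTRY: dict[str, tuple[bool, Callable[[], dict]]] = {
    # name -> (has_network_file, predicate factory)
    "nar_par": (False, _nar_par_predicates),
    "negative_feedback": (True, _negative_feedback_predicates),
    "oscillator": (True, _oscillator_predicates),
    "basal_error": (False, _basal_error_predicates),
    "irma4": (True, _irma_predicates),
    "ffl_cascade": (True, _ffl_predicates),
    "kalman_demo": (False, _kalman_predicates),
    "six_node": (True, _six_node_predicates),
}


def case_study(name: str) -> CaseStudy:
    """Return the fully parameterized case study registered under ``name``."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown case study {name!r}; choose from {CASE_STUDY_NAMES}")
    has_network, factory = _REGISTRY[name]
    raw = _load_json(name)
    network = NetworkSpec.model_validate(raw) if has_network else None
    params = raw.get("params", {}) if not has_network else _derived_params(name, network)
    return CaseStudy(name=name, network=network, params=params, predicates=factory())


def _derived_params(name: str, network: NetworkSpec) -> dict:
    if name == "oscillator":
        return _oscillator_params(network)
    return {}
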