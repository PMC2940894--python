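"""Directed gene-network specifications and their JSON serialization.

A :class:`NetworkSpec` describes a linearized gene network: one node per
gene with a degradation/dilution constant ``D`` (per minute) and a basal
production rate ``F0`` (molecules/min), directed regulation edges with a
sign and a linear strength ``F`` (per minute), and constant external drives
(the product ``f_xy * x`` of an upstream production constant and input
concentration, molecules/min). Self-edges encode autoregulation.

The same spec feeds both the transfer-function reduction (frequency domain)
and the state-space builders (time domain): the network's state matrix has
``-D_i`` (plus any self-edge ±H) on the diagonal and ``±F`` for each edge
``source -> target`` in row *target*, column *source*.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = ["Node", "Edge", "NetworkSpec", "load_network", "save_network"]

SCHEMA_VERSION = 1


class Node(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    degradation: float = Field(gt=0, description="degradation/dilution constant D, per minute")
    basal: float = Field(default=0.0, ge=0, description="basal production rate F0, molecules/min")


class Edge(BaseModel):
    model_config = ConfigDict(extra="forbid")

    source: str
    target: str
    sign: Literal["activation", "repression"]
    strength: float = Field(gt=0, description="linear regulation strength F, per minute")

    @property
    def signed_strength(self) -> float:
        return self.strength if self.sign == "activation" else -self.strength


class NetworkSpec(BaseModel):
    """A validated gene-network description.

    ``inputs`` maps node names to constant external drives; ``input_node``
    and ``output_node`` designate the ports used when reducing the network
    to a single transfer function.
    """

    model_config = ConfigDict(extra="forbid")

    version: int = SCHEMA_VERSION
    name: str = ""
    nodes: list[Node]
    edges: list[Edge] = Field(default_factory=list)
    inputs: dict[str, float] = Field(default_factory=dict)
    input_node: Optional[str] = None
    output_node: Optional[str] = None

    @model_validator(mode="after")
    def _check_references(self) -> "NetworkSpec":
        if self.version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {self.version} (expected {SCHEMA_VERSION})")
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        known = set(names)
        for e in self.edges:
            for end in (e.source, e.target):
                if end not in known:
                    raise ValueError(f"edge references unknown node {end!r}")
        for port in (self.input_node, self.output_node):
            if port is not None and port not in known:
                raise ValueError(f"designated port {port!r} is not a node")
        for k in self.inputs:
            if k not in known:
                raise ValueError(f"input drive for unknown node {k!r}")
        return self

    # -- matrix view -------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def state_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(A, b)`` with ``ds/dt = A s + b`` under the constant drives.

        ``b`` collects external drives plus basal rates.
        """
        names = self.node_names
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        A = np.zeros((n, n))
        for i, node in enumerate(self.nodes):
            A[i, i] = -node.degradation
        for e in self.edges:
            A[idx[e.target], idx[e.source]] += e.signed_strength
        b = np.array([self.inputs.get(nm, 0.0) for nm in names])
        b += np.array([node.basal for node in self.nodes])
        return A, b

    # -- serialization -----------------------------------------------------

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.model_dump(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"not valid JSON: {exc}") from exc
        return cls.model_validate(data)


def load_network(path: str | Path) -> NetworkSpec:
    """Load and validate a NetworkSpec JSON file."""
    path = Path(path)
    try:
        return NetworkSpec.from_json(path.read_text())
    except (ValidationError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_network(spec: NetworkSpec, path: str | Path) -> None:
    Path(path).write_text(spec.to_json() + "\n")
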