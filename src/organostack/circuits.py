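"""Circuit descriptions: liquids, stacks, resistance network — YAML/JSON I/O.

A ``CircuitSpec`` is the structured input shared by the flow-direction,
network-solve and feeding simulations.  The on-disk schema (YAML or JSON)::

    environment:
      gravity: 9.81            # m/s^2
      fc40_density: 1855.0     # kg/m^3
      dish_height_mm: 13.0
    medium:
      name: medium
      density: 998.0           # kg/m^3
      viscosity_mPa_s: 0.89
      gamma_vs_fc40_mN_per_m: 23.0
    stacks:
      A:
        elements:
          - {outer_diameter_mm: 10.0, inner_diameter_mm: 5.0,
             thickness_mm: 1.0, material: hydrophilic}
        cap_height_mm: 0.0     # optional; omit for no cap
    network:
      edges:
        - {a: A, b: B, resistance: 3.4e9, label: paper, wanted: true}
      pressures: {B: 0.0}      # Pa, optional
      inflows: {A: 1.0e-11}    # m^3/s, optional

Dimensions are in the bench units practitioners use (mm, mPa*s, mN/m);
they are converted to SI on load.  Resistances are given directly in
Pa*s/m^3 (permeabilities of papers and gels are not tabulated anywhere
authoritative, so shipped example values are order-of-magnitude
placeholders only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .darcy_network import Edge, HydraulicNetwork
from .fluid_mechanics import (
    AnnularElement,
    Environment,
    Liquid,
    StackSpec,
    cap_from_height,
)

__all__ = ["CircuitSpec", "load_circuit", "save_circuit"]

MM = 1e-3


@dataclass
class CircuitSpec:
    """A full circuit: environment, stacks keyed by label, resistance network."""

    environment: Environment
    stacks: dict[str, StackSpec] = field(default_factory=dict)
    network: HydraulicNetwork = field(default_factory=HydraulicNetwork)
    name: str = ""
    meta: dict = field(default_factory=dict)

    def stack_pair(self) -> tuple[StackSpec, StackSpec]:
        """The two stacks of a simple two-stack circuit, in label order."""
        if len(self.stacks) != 2:
            raise ValueError(
                f"circuit has {len(self.stacks)} stacks; expected exactly 2")
        labels = sorted(self.stacks)
        return self.stacks[labels[0]], self.stacks[labels[1]]

    # --- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        env = self.environment
        med = env.medium
        d: dict = {
            "name": self.name,
            "meta": dict(self.meta),
            "environment": {
                "gravity": env.gravity,
                "fc40_density": env.fc40_density,
                "dish_height_mm": env.dish_height / MM,
            },
            "medium": {
                "name": med.name,
                "density": med.density,
                "viscosity_mPa_s": med.viscosity * 1e3,
                "gamma_vs_fc40_mN_per_m": (
                    med.gamma_vs_fc40 * 1e3 if med.gamma_vs_fc40 else None),
            },
            "stacks": {},
            "network": {
                "edges": [
                    {"a": e.node_a, "b": e.node_b, "resistance": e.resistance,
                     "label": e.label, "wanted": e.wanted}
                    for e in self.network.edges
                ],
                "pressures": dict(self.network.pressures),
                "inflows": dict(self.network.inflows),
            },
        }
        for label, stack in self.stacks.items():
            s: dict = {"elements": [
                {"outer_diameter_mm": el.outer_diameter / MM,
                 "inner_diameter_mm": el.inner_diameter / MM,
                 "thickness_mm": el.thickness / MM,
                 "material": el.material,
                 **({"permeability": el.permeability}
                    if el.permeability is not None else {})}
                for el in stack.elements
            ]}
            if stack.cap is not None:
                s["cap_height_mm"] = stack.cap.height / MM
            d["stacks"][label] = s
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitSpec":
        med_d = d.get("medium", {})
        gamma = med_d.get("gamma_vs_fc40_mN_per_m")
        medium = Liquid(
            name=med_d.get("name", "medium"),
            density=float(med_d.get("density", 998.0)),
            viscosity=float(med_d.get("viscosity_mPa_s", 0.89)) * 1e-3,
            gamma_vs_fc40=(float(gamma) * 1e-3 if gamma is not None else None),
        )
        env_d = d.get("environment", {})
        env = Environment(
            gravity=float(env_d.get("gravity", 9.81)),
            fc40_density=float(env_d.get("fc40_density", 1855.0)),
            dish_height=float(env_d.get("dish_height_mm", 13.0)) * MM,
            medium=medium,
        )
        stacks: dict[str, StackSpec] = {}
        for label, s in d.get("stacks", {}).items():
            elements = tuple(
                AnnularElement(
                    outer_diameter=float(el["outer_diameter_mm"]) * MM,
                    inner_diameter=float(el["inner_diameter_mm"]) * MM,
                    thickness=float(el["thickness_mm"]) * MM,
                    material=el.get("material", "hydrophilic"),
                    permeability=(float(el["permeability"])
                                  if el.get("permeability") is not None else None),
                )
                for el in s["elements"]
            )
            cap = None
            if s.get("cap_height_mm") is not None:
                base = elements[-1].inner_diameter / 2.0
                cap = cap_from_height(base, float(s["cap_height_mm"]) * MM)
            stacks[label] = StackSpec(elements=elements, cap=cap, label=label)
        net_d = d.get("network", {})
        net = HydraulicNetwork(
            edges=[Edge(e["a"], e["b"], float(e["resistance"]),
                        e.get("label", ""), bool(e.get("wanted", False)))
                   for e in net_d.get("edges", [])],
            pressures={k: float(v) for k, v in net_d.get("pressures", {}).items()},
            inflows={k: float(v) for k, v in net_d.get("inflows", {}).items()},
        )
        return cls(environment=env, stacks=stacks, network=net,
                   name=d.get("name", ""), meta=dict(d.get("meta", {})))


def load_circuit(path: Union[str, Path]) -> CircuitSpec:
    """Read a CircuitSpec from YAML (``.yaml``/``.yml``) or JSON (``.json``)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return CircuitSpec.from_dict(json.loads(text))
    return CircuitSpec.from_dict(yaml.safe_load(text))


def save_circuit(spec: CircuitSpec, path: Union[str, Path]) -> None:
    """Write a CircuitSpec as YAML or JSON, chosen by file suffix."""
    path = Path(path)
    d = spec.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
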