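"""End-to-end pipeline: graph analysis, algebra, simulation, sweep, one report.

``run_full_pipeline`` executes every stage on a reaction network (the
built-in cholesterol network by default) and assembles a deterministic,
JSON-serialisable analysis report.  Symbolic expressions are serialised in
a canonical sorted-monomial string form so reports are diffable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import sympy

from . import __version__
from .cholesterol import cholesterol_network, cholesterol_subnetworks, reference_fixture
from .crn import CRN, ParameterSet, parse_reactions
from .graph import (
    GraphSummary,
    SubnetworkPartition,
    deficiency,
    shinar_feinberg_screen,
    verify_independent_decomposition,
)
from .mass_action import build_ode_system, closed_form_steady_state
from .rpa import rpa_report
from .dynamics import simulate, stability_sweep, verify_rpa
from .synthetic import make_step_protocol

__all__ = ["AnalysisReport", "run_full_pipeline", "default_config"]


def default_config() -> dict:
    return {
        "network": "cholesterol",
        "run_simulation": True,
        "run_sweep": True,
        "protocol": {"levels": [1.0, 2.0, 4.0], "segment_length": 1500.0},
        "sweep": {
            "n_samples": 10_000,
            "n_trials": 10,
            "low": 1.0,
            "high": 50.0,
            "mode": "formal",
            "sample_input": True,
        },
    }


@dataclass(frozen=True)
class AnalysisReport:
    """Consolidated machine-readable pipeline output."""

    sections: Mapping[str, Any]

    def to_dict(self) -> dict:
        return dict(self.sections)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=False)


def _canonical(expr) -> str:
    return sympy.sstr(sympy.expand(expr), order="lex")


def run_full_pipeline(
    config: Mapping[str, Any] | None = None, seed: int = 0
) -> AnalysisReport:
    """Run analyze -> odes -> rpa -> simulate -> sweep and assemble the report."""
    cfg = default_config()
    for key, value in (config or {}).items():
        if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value

    if cfg["network"] == "cholesterol":
        crn = cholesterol_network()
        subnets = cholesterol_subnetworks()
    else:
        with open(cfg["network"]) as fh:
            crn = parse_reactions(fh.read(), name=str(cfg["network"]))
        subnets = {}

    sections: dict[str, Any] = {}
    full = deficiency(crn)
    graph_sec: dict[str, Any] = {"full_network": full.to_dict()}
    graph_sec["notes"] = [
        "the stoichiometric rank is computed exactly over the rationals and "
        f"cannot exceed the species count ({len(crn.species)})"
    ]
    if subnets:
        top = SubnetworkPartition(
            {k: subnets[k] for k in ("subnetwork_1", "subnetwork_2")}
        )
        decomp = verify_independent_decomposition(crn, top)
        graph_sec["decomposition"] = decomp.to_dict()
        sub1 = crn.subnetwork(subnets["subnetwork_1"], "subnetwork_1")
        refine = verify_independent_decomposition(
            sub1,
            SubnetworkPartition(
                {
                    "subnetwork_1A": tuple(
                        subnets["subnetwork_1"].index(i)
                        for i in subnets["subnetwork_1A"]
                    ),
                    "subnetwork_1B": tuple(
                        subnets["subnetwork_1"].index(i)
                        for i in subnets["subnetwork_1B"]
                    ),
                }
            ),
        )
        graph_sec["subnetwork_1_refinement"] = refine.to_dict()
        graph_sec["shinar_feinberg"] = {
            "subnetwork_1": shinar_feinberg_screen(sub1).to_dict(),
            "subnetwork_1A": shinar_feinberg_screen(
                crn.subnetwork(subnets["subnetwork_1A"], "subnetwork_1A")
            ).to_dict(),
        }
    sections["graph"] = graph_sec

    odes = build_ode_system(crn)
    sections["odes"] = {
        "variables": [v.name for v in odes.variables],
        "inputs": [u.name for u in odes.inputs],
        "rhs": {v.name: _canonical(f) for v, f in zip(odes.variables, odes.rhs)},
    }
    steady = closed_form_steady_state(odes)
    sections["steady_state"] = {
        name: _canonical(expr) for name, expr in steady.by_name().items()
    }

    algebra = rpa_report(crn, odes)
    sections["rpa"] = algebra.to_dict()

    if cfg["run_simulation"]:
        params, initial = reference_fixture() if cfg["network"] == "cholesterol" else (None, None)
        protocol = make_step_protocol(
            tuple(cfg["protocol"]["levels"]), cfg["protocol"]["segment_length"]
        )
        traj = simulate(odes, params, initial, protocol)
        setpoints = {
            name: float(
                sympy.sympify(expr).subs(odes.substitutions(params))
                if isinstance(expr, str)
                else expr.subs(odes.substitutions(params))
            )
            for name, expr in algebra.rpa_species.items()
        }
        verdicts = verify_rpa(traj, odes, setpoints)
        sections["simulation"] = {
            "protocol_levels": list(protocol.levels),
            "segment_length": cfg["protocol"]["segment_length"],
            "verdicts": {k: v.verdict for k, v in verdicts.items()},
            "segment_end_values": {
                k: list(v.end_values) for k, v in verdicts.items()
            },
        }
        sim_rpa = sorted(
            k for k, v in verdicts.items() if v.verdict == "rpa"
        )
        alg_rpa = sorted(algebra.rpa_species)
        sections["simulation"]["consistent_with_algebra"] = sim_rpa == alg_rpa

    if cfg["run_sweep"]:
        sw = cfg["sweep"]
        result = stability_sweep(
            odes,
            n_samples=sw["n_samples"],
            n_trials=sw["n_trials"],
            seed=seed,
            bounds=(sw["low"], sw["high"]),
            sample_input=sw["sample_input"],
            mode=sw["mode"],
            steady_state=steady,
        )
        sections["sweep"] = result.to_dict()

    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    sections["provenance"] = {
        "package": "crnrpa",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "numpy": np.__version__,
        "sympy": sympy.__version__,
    }
    return AnalysisReport(sections=sections)
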