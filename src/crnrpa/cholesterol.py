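"""Built-in cholesterol homeostasis network and its reference inputs.

The network couples SREBP-mediated transcriptional control, receptor-mediated
LDL uptake, HMGCR-driven biosynthesis, esterification and efflux of cellular
cholesterol.  Fourteen species take part in 22 biochemical processes; one of
them, the extracellular lipoprotein cholesterol ``CL``, is the chemostatted
input to which the intracellular pools must adapt.  The PCSK9-mediated LDLR
degradation chain ``P+R -> P -> 0`` contributes two irreversible reactions,
so the reaction list has 23 entries.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .crn import CRN, ParameterSet, parse_reactions

__all__ = [
    "cholesterol_network",
    "cholesterol_reaction_text",
    "reference_fixture",
    "cholesterol_subnetworks",
    "SUBNETWORK_1",
    "SUBNETWORK_2",
    "SUBNETWORK_1A",
    "SUBNETWORK_1B",
]

# Reaction indices (0-based, file order) of the RPA-conferring subnetwork and
# its algebraically independent refinement.  Subnetwork 1 collects the
# antithetic sequestration cycle (production of the SREBP/Scap/Insig complex,
# its retention by lumenal cholesterol, the release of active cholesterol)
# together with the passive cholesterol exchange fluxes; Subnetwork 2 is the
# remainder of the network.
SUBNETWORK_1: tuple[int, ...] = (0, 21, 20, 12, 13, 14, 15, 16)
SUBNETWORK_2: tuple[int, ...] = tuple(i for i in range(23) if i not in SUBNETWORK_1)
SUBNETWORK_1A: tuple[int, ...] = (0, 21, 20)
SUBNETWORK_1B: tuple[int, ...] = (12, 13, 14, 15, 16)


def cholesterol_reaction_text() -> str:
    """The packaged reaction file, in the plain-text dialect."""
    return resources.files("crnrpa.data").joinpath("cholesterol.crn").read_text()


def cholesterol_network() -> CRN:
    """The 14-species cholesterol homeostasis CRN with ``CL`` chemostatted."""
    crn = parse_reactions(cholesterol_reaction_text(), name="cholesterol")
    assert len(crn.species) == 14 and len(crn.reactions) == 23
    return crn


def reference_fixture() -> tuple[ParameterSet, dict[str, float]]:
    """Reference rate constants and initial concentrations.

    Returns the 23 rate-constant values and the 13 dynamic-species initial
    values used for the step-response demonstration; the input level
    defaults to ``CL = 1``.
    """
    raw = yaml.safe_load(
        resources.files("crnrpa.data").joinpath("reference_parameters.yaml").read_text()
    )
    params = ParameterSet(
        {k: float(v) for k, v in raw["parameters"].items()}, input_level=1.0
    )
    initial = {k: float(v) for k, v in raw["initial_state"].items()}
    return params, initial


def cholesterol_subnetworks() -> dict[str, tuple[int, ...]]:
    """Named reaction-index sets of the reconstructed decomposition.

    ``subnetwork_1``/``subnetwork_2`` partition the full network;
    ``subnetwork_1A``/``subnetwork_1B`` partition subnetwork 1.
    """
    return {
        "subnetwork_1": SUBNETWORK_1,
        "subnetwork_2": SUBNETWORK_2,
        "subnetwork_1A": SUBNETWORK_1A,
        "subnetwork_1B": SUBNETWORK_1B,
    }
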