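"""Synthetic inputs: random parameter sets, step protocols, random small CRNs.

The parameter sampler reproduces the sweep's sampling design — every rate
constant i.i.d. uniform on an open interval, (1, 50) by default — and the
random CRN generator produces small networks (biased toward complexes of
size at most two, mirroring the bimolecular structure of the cholesterol
fixture) for oracle-based testing of the graph and algebra machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crn import CRN, Complex, ParameterSet, Reaction, ValidationError
from .dynamics import (
    DEFAULT_SEGMENT_LENGTH,
    DEFAULT_STEP_LEVELS,
    StepProtocol,
    _open_uniform,
)

__all__ = [
    "SamplerConfig",
    "RandomCrnConfig",
    "sample_parameter_sets",
    "make_step_protocol",
    "random_crn",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Design of the random-parameter draw."""

    n: int
    seed: int = 0
    low: float = 1.0
    high: float = 50.0
    sample_input: bool = True
    input_level: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValidationError("need 0 < low < high")
        if self.n < 0:
            raise ValidationError("n must be non-negative")


def sample_parameter_sets(crn: CRN, config: SamplerConfig) -> list[ParameterSet]:
    """Draw ``config.n`` parameter sets for the CRN's rate symbols.

    Each rate constant — and the input level when ``sample_input`` is set —
    is i.i.d. uniform on the open interval (low, high).  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))
    symbols = crn.rate_symbols
    draws = _open_uniform(rng, (config.low, config.high), (config.n, len(symbols)))
    if config.sample_input:
        levels = _open_uniform(rng, (config.low, config.high), (config.n,))
    else:
        levels = np.full(config.n, config.input_level)
    return [
        ParameterSet(dict(zip(symbols, map(float, row))), input_level=float(lv))
        for row, lv in zip(draws, levels)
    ]


def make_step_protocol(
    levels: tuple[float, ...] = DEFAULT_STEP_LEVELS,
    segment_length: float = DEFAULT_SEGMENT_LENGTH,
) -> StepProtocol:
    """Step protocol switching between the given levels at regular intervals."""
    if not levels:
        raise ValidationError("need at least one input level")
    if any(lv <= 0 for lv in levels):
        raise ValidationError("input levels must be positive")
    steps = tuple((i * segment_length, float(lv)) for i, lv in enumerate(levels))
    return StepProtocol(steps, end_time=len(levels) * segment_length)


@dataclass(frozen=True)
class RandomCrnConfig:
    """Design of a random small CRN draw."""

    n_species: int = 4
    n_reactions: int = 5
    max_multiplicity: int = 2
    max_complex_size: int = 2
    seed: int = 0
    n_chemostatted: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_reactions, self.max_multiplicity,
               self.max_complex_size) < 1:
            raise ValidationError("config values must be positive")
        if not 0 <= self.n_chemostatted < self.n_species:
            raise ValidationError("invalid chemostatted count")


def random_crn(config: RandomCrnConfig) -> CRN:
    """A valid random CRN: distinct reactions, reactant != product, seeded.

    Complexes are drawn with sizes biased toward one and two species so
    that generated networks remain hand-checkable.  Raises when the
    requested number of distinct reactions cannot be placed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed]))
    species = tuple(f"X{i+1}" for i in range(config.n_species))

    def draw_complex() -> Complex:
        size = int(rng.integers(0, config.max_complex_size + 1))
        if size == 0 and rng.random() > 0.25:  # zero complex stays uncommon
            size = 1
        chosen = rng.choice(config.n_species, size=min(size, config.n_species),
                            replace=False)
        terms = {
            species[int(i)]: int(rng.integers(1, config.max_multiplicity + 1))
            for i in chosen
        }
        return Complex.from_terms(terms)

    reactions: list[Reaction] = []
    seen: set[tuple[Complex, Complex]] = set()
    attempts = 0
    while len(reactions) < config.n_reactions:
        attempts += 1
        if attempts > 200 * config.n_reactions:
            raise ValidationError(
                f"cannot place {config.n_reactions} distinct reactions "
                f"with {config.n_species} species"
            )
        reactant, product = draw_complex(), draw_complex()
        if reactant == product or (reactant, product) in seen:
            continue
        seen.add((reactant, product))
        reactions.append(
            Reaction(reactant, product, f"r{len(reactions) + 1}")
        )
    chemostatted = frozenset(species[: config.n_chemostatted])
    return CRN(
        species=species,
        reactions=tuple(reactions),
        chemostatted=chemostatted,
        name=f"random-{config.seed}",
    )
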