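"""Synthetic respondents: a latent-ability noise model on the slider scale.

Each simulated respondent has a standard-normal latent ability ``a``.  On a
trial testing dimension ``d`` the final slider is the target plus Gaussian
reproduction noise with standard deviation

    sd = sigma_d * exp(-kappa * a)            (match trials)
    sd = sigma_d * exp(-kappa * a) * m        (memory trials, m >= 1)

clipped to the 0-100 scale, so abler respondents land closer to the target
and single-playback (memory) trials are noisier than unlimited-playback
(match) trials.  With probability ``p_stick`` the respondent leaves the
slider at its default resting position, which the scoring pipeline treats
as a real (scored) response.  Noise acts on the slider scale, not on the
acoustic parameters, because responses and scores both live on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .protocol import DIMENSIONS, Item, ResponseMatrix, SessionConfig

__all__ = [
    "DEFAULT_SIGMA",
    "RespondentModel",
    "CohortSpec",
    "CohortResult",
    "simulate_response",
    "simulate_cohort",
    "simulate_retest",
]

#: Baseline reproduction noise (slider units) per dimension.
DEFAULT_SIGMA: Mapping[str, float] = {dim: 15.0 for dim in DIMENSIONS}


@dataclass(frozen=True)
class RespondentModel:
    """Noise model for one respondent."""

    ability: float = 0.0
    sigma_dim: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    kappa: float = 1.0
    memory_multiplier: float = 1.5
    p_stick: float = 0.05

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.memory_multiplier < 1:
            raise ValueError("memory_multiplier must be >= 1")
        if not 0 <= self.p_stick <= 1:
            raise ValueError("p_stick must be a probability")

    def noise_sd(self, block: str, variant: str) -> float:
        sd = self.sigma_dim[block] * np.exp(-self.kappa * self.ability)
        if variant == "memory":
            sd *= self.memory_multiplier
        return sd


def simulate_response(
    model: RespondentModel,
    item: Item,
    rng: np.random.Generator,
    default_slider: float = 50.0,
    mean_extra_playbacks: float = 2.0,
) -> dict:
    """One trial's response as a response-table row (dict)."""
    stick = rng.random() < model.p_stick
    if stick:
        final = default_slider
    else:
        sd = model.noise_sd(item.block, item.variant)
        final = float(np.clip(item.target_slider + rng.normal(0.0, sd), 0.0, 100.0))
    if item.variant == "memory":
        n_stim = 1
    else:
        n_stim = 1 + int(rng.poisson(mean_extra_playbacks))
    n_repro = 0 if stick else 1 + int(rng.poisson(mean_extra_playbacks))
    return {
        "item_id": item.item_id,
        "final_slider": final,
        "moved": not stick,
        "n_stimulus_playbacks": n_stim,
        "n_reproduction_playbacks": n_repro,
    }


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of independent synthetic respondents."""

    n_respondents: int = 95
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    model: RespondentModel = field(default_factory=RespondentModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("need at least one respondent")


@dataclass(frozen=True)
class CohortResult:
    """Simulated responses together with the generating abilities."""

    responses: ResponseMatrix
    abilities: pd.Series  # indexed by respondent_id


def _respondent_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


def _simulate_occasion(
    abilities: pd.Series,
    spec: CohortSpec,
    session: SessionConfig,
    rng: np.random.Generator,
) -> ResponseMatrix:
    rows = []
    for rid, ability in abilities.items():
        model = replace(spec.model, ability=float(ability))
        for item in session.items:
            row = simulate_response(
                model, item, rng, default_slider=session.default_slider_position
            )
            row["respondent_id"] = rid
            rows.append(row)
    return ResponseMatrix(pd.DataFrame(rows))


def simulate_cohort(spec: CohortSpec, session: SessionConfig) -> CohortResult:
    """Simulate one testing occasion for a cohort; reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    ids = _respondent_ids(spec.n_respondents)
    abilities = pd.Series(
        spec.ability_mean + spec.ability_sd * rng.standard_normal(len(ids)),
        index=ids,
        name="ability",
    )
    return CohortResult(
        responses=_simulate_occasion(abilities, spec, session, rng),
        abilities=abilities,
    )


def simulate_retest(
    spec: CohortSpec, session: SessionConfig
) -> tuple[CohortResult, CohortResult]:
    """Two occasions with the same abilities but independent noise draws."""
    rng = np.random.default_rng(spec.seed)
    ids = _respondent_ids(spec.n_respondents)
    abilities = pd.Series(
        spec.ability_mean + spec.ability_sd * rng.standard_normal(len(ids)),
        index=ids,
        name="ability",
    )
    first = _simulate_occasion(abilities, spec, session, rng)
    second = _simulate_occasion(abilities, spec, session, rng)
    return (
        CohortResult(responses=first, abilities=abilities),
        CohortResult(responses=second, abilities=abilities),
    )
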