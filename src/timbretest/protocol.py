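"""Test structure: items, parameter sets, sessions, and response tables.

The full test has three blocks, one per timbre dimension, each consisting of
one training trial, five match trials (unlimited stimulus playback) and ten
memory trials (single playback), i.e. 45 scored items plus 3 training items.
Five parameter sets — combinations of slider targets for the three
dimensions crossed with five pitches via a Latin square — provide the trial
targets; every block presents all five sets among its match items and each
set twice among its memory items, in a seed-permuted order.

The short test keeps only match trials and drops the two match items whose
targets sit at the slider's default position (one envelope, one flux),
leaving 13 items: 4 envelope, 4 flux, 5 centroid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ResponseParseError,
    ResponseValidationError,
    SessionConfigError,
    ValidationWarning,
)
from .synthesis import DEFAULT_PITCH_SET, StimulusSpec, note_to_hz

__all__ = [
    "DIMENSIONS",
    "VARIANTS",
    "TARGET_LEVELS",
    "DEFAULT_SLIDER_POSITION",
    "DEFAULT_SHORT_EXCLUSIONS",
    "ParameterSet",
    "Item",
    "SessionConfig",
    "ResponseMatrix",
    "default_parameter_sets",
    "build_full_session",
    "build_short_session",
    "read_responses",
    "write_responses",
    "validate_against_session",
]

DIMENSIONS = ("envelope", "flux", "centroid")
VARIANTS = ("match", "memory", "training")

#: Slider targets of the five parameter sets, spanning the 0-100 scale.
TARGET_LEVELS = (10.0, 30.0, 50.0, 70.0, 90.0)

#: Where the response slider starts each trial; unmoved sliders score here.
DEFAULT_SLIDER_POSITION = 50.0

N_MATCH_PER_BLOCK = 5
N_MEMORY_PER_BLOCK = 10


@dataclass(frozen=True)
class ParameterSet:
    """One of the five target combinations (sliders per dimension + pitch)."""

    index: int  # 1..5
    envelope: float
    flux: float
    centroid: float
    pitch: str

    def target_for(self, dimension: str) -> float:
        return {"envelope": self.envelope, "flux": self.flux, "centroid": self.centroid}[
            dimension
        ]


def default_parameter_sets(
    levels: Sequence[float] = TARGET_LEVELS,
    pitches: Sequence[str] = DEFAULT_PITCH_SET,
) -> tuple[ParameterSet, ...]:
    """Latin-square mix-match of slider levels and pitches into five sets.

    Set i takes envelope level i, flux level i+1, centroid level i+2 and
    pitch i+3 (cyclically), so each dimension and the pitch each run through
    all five levels across the sets.
    """
    k = len(levels)
    return tuple(
        ParameterSet(
            index=i + 1,
            envelope=levels[i],
            flux=levels[(i + 1) % k],
            centroid=levels[(i + 2) % k],
            pitch=pitches[(i + 3) % k],
        )
        for i in range(k)
    )


#: The envelope and flux match items whose target equals the default slider
#: position: respondents can score well there without touching the slider,
#: so these low-discriminability items are dropped from the short version
#: (the centroid block keeps all five match items).
DEFAULT_SHORT_EXCLUSIONS = ("envelope-match-set3", "flux-match-set2")


@dataclass(frozen=True)
class Item:
    """One trial: which dimension is tested, its target, and the pitch."""

    item_id: str
    block: str  # envelope | flux | centroid
    variant: str  # match | memory | training
    target_slider: float
    pitch: str
    param_set_index: int

    @property
    def scored(self) -> bool:
        return self.variant != "training"


def stimulus_for_item(
    item: Item, parameter_sets: Sequence[ParameterSet] | None = None, **spec_kwargs
) -> StimulusSpec:
    """Build the target stimulus for an item.

    The tested dimension takes the item's target slider; the two untested
    dimensions take the parameter set's values, so the reproduction tone and
    the stimulus tone differ only along the tested dimension.
    """
    sets = parameter_sets or default_parameter_sets()
    pset = next(p for p in sets if p.index == item.param_set_index)
    sliders = {dim: pset.target_for(dim) for dim in DIMENSIONS}
    sliders[item.block] = item.target_slider
    return StimulusSpec(
        f0_hz=note_to_hz(item.pitch),
        envelope_slider=sliders["envelope"],
        flux_slider=sliders["flux"],
        centroid_slider=sliders["centroid"],
        **spec_kwargs,
    )


@dataclass(frozen=True)
class SessionConfig:
    """An ordered list of items plus session-level settings."""

    version: str  # "full" | "short"
    items: tuple[Item, ...]
    default_slider_position: float = DEFAULT_SLIDER_POSITION
    seed: int | None = None

    def scored_items(self) -> tuple[Item, ...]:
        return tuple(it for it in self.items if it.scored)

    def item(self, item_id: str) -> Item:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def targets(self) -> dict[str, float]:
        return {it.item_id: it.target_slider for it in self.scored_items()}

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "default_slider_position": self.default_slider_position,
            "seed": self.seed,
            "items": [asdict(it) for it in self.items],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SessionConfig":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            version=payload["version"],
            items=tuple(Item(**it) for it in payload["items"]),
            default_slider_position=payload.get(
                "default_slider_position", DEFAULT_SLIDER_POSITION
            ),
            seed=payload.get("seed"),
        )


def _block_items(
    block: str,
    sets: Sequence[ParameterSet],
    rng: np.random.Generator,
) -> list[Item]:
    def make(variant: str, pset: ParameterSet, suffix: str = "") -> Item:
        return Item(
            item_id=f"{block}-{variant}-set{pset.index}{suffix}",
            block=block,
            variant=variant,
            target_slider=pset.target_for(block),
            pitch=pset.pitch,
            param_set_index=pset.index,
        )

    items = [make("training", sets[0])]
    match_order = rng.permutation(len(sets))
    items.extend(make("match", sets[i]) for i in match_order)
    # memory trials reuse the five sets twice, in a fresh permuted order
    memory_pool = [(i, "a") for i in range(len(sets))] + [
        (i, "b") for i in range(len(sets))
    ]
    memory_order = rng.permutation(len(memory_pool))
    items.extend(
        make("memory", sets[memory_pool[j][0]], memory_pool[j][1])
        for j in memory_order
    )
    return items


def build_full_session(
    seed: int,
    parameter_sets: Sequence[ParameterSet] | None = None,
    default_slider_position: float = DEFAULT_SLIDER_POSITION,
) -> SessionConfig:
    """Build the full 45-scored-item session (plus 3 training items)."""
    sets = tuple(parameter_sets or default_parameter_sets())
    rng = np.random.default_rng(seed)
    items: list[Item] = []
    for block in DIMENSIONS:
        items.extend(_block_items(block, sets, rng))
    return SessionConfig(
        version="full",
        items=tuple(items),
        default_slider_position=default_slider_position,
        seed=seed,
    )


def build_short_session(
    flagged_items: Iterable[str] | None = None,
    seed: int = 0,
    parameter_sets: Sequence[ParameterSet] | None = None,
    max_flagged: int = 2,
    default_slider_position: float = DEFAULT_SLIDER_POSITION,
) -> SessionConfig:
    """Build the short, match-only session.

    Starts from the full session's match items, removing the flagged items
    (by default the two whose targets coincide with the resting slider).
    """
    flagged = tuple(DEFAULT_SHORT_EXCLUSIONS if flagged_items is None else flagged_items)
    if len(flagged) > max_flagged:
        raise SessionConfigError(
            f"{len(flagged)} items flagged but at most {max_flagged} may be excluded"
        )
    full = build_full_session(seed, parameter_sets, default_slider_position)
    match_ids = {it.item_id for it in full.items if it.variant == "match"}
    unknown = set(flagged) - match_ids
    if unknown:
        raise SessionConfigError(f"flagged items are not match items: {sorted(unknown)}")
    items = tuple(
        it
        for it in full.items
        if it.variant == "match" and it.item_id not in flagged
    )
    return SessionConfig(
        version="short",
        items=items,
        default_slider_position=default_slider_position,
        seed=seed,
    )


RESPONSE_COLUMNS = (
    "respondent_id",
    "item_id",
    "final_slider",
    "moved",
    "n_stimulus_playbacks",
    "n_reproduction_playbacks",
)


class ResponseMatrix:
    """Respondents x items table of trial responses.

    Wraps a long-format DataFrame with one row per (respondent, item); an
    unmoved slider is a real observation (``moved`` False), never a missing
    value.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
        if missing:
            raise ResponseParseError(f"response table missing columns: {missing}")
        table = table.loc[:, list(RESPONSE_COLUMNS)].copy()
        sliders = pd.to_numeric(table["final_slider"], errors="coerce")
        bad = table.index[sliders.isna()]
        if len(bad):
            raise ResponseParseError(
                f"non-numeric final_slider at rows {list(bad[:5])}"
            )
        out_of_range = table.index[(sliders < 0) | (sliders > 100)]
        if len(out_of_range):
            raise ResponseValidationError(
                f"final_slider outside [0, 100] at rows {list(out_of_range[:5])}"
            )
        table["final_slider"] = sliders.astype(float)
        table["moved"] = table["moved"].astype(bool)
        for col in ("n_stimulus_playbacks", "n_reproduction_playbacks"):
            counts = pd.to_numeric(table[col], errors="coerce")
            if counts.isna().any() or (counts < 0).any():
                raise ResponseValidationError(f"{col} must be a non-negative integer")
            table[col] = counts.astype(int)
        dup = table.duplicated(subset=["respondent_id", "item_id"])
        if dup.any():
            raise ResponseValidationError("duplicate (respondent, item) rows")
        self.table = table.reset_index(drop=True)

    @property
    def respondents(self) -> list:
        return list(pd.unique(self.table["respondent_id"]))

    @property
    def items(self) -> list[str]:
        return list(pd.unique(self.table["item_id"]))

    def pivot_sliders(self) -> pd.DataFrame:
        return self.table.pivot(
            index="respondent_id", columns="item_id", values="final_slider"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        a = self.table.sort_values(["respondent_id", "item_id"]).reset_index(drop=True)
        b = other.table.sort_values(["respondent_id", "item_id"]).reset_index(drop=True)
        return a.equals(b)


def write_responses(matrix: ResponseMatrix, path) -> None:
    matrix.table.to_csv(path, index=False)


def read_responses(path) -> ResponseMatrix:
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ResponseParseError(f"cannot parse {path}: {exc}") from exc
    return ResponseMatrix(table)


def validate_against_session(matrix: ResponseMatrix, session: SessionConfig) -> None:
    """Check a response table against a session; warn on suspicious rows.

    Raises KeyError for responses to unknown items and warns when a memory
    trial records more than one stimulus playback.
    """
    known = {it.item_id for it in session.items}
    unknown = set(matrix.items) - known
    if unknown:
        raise KeyError(f"responses reference unknown items: {sorted(unknown)}")
    memory_ids = {it.item_id for it in session.items if it.variant == "memory"}
    rows = matrix.table
    offending = rows[
        rows["item_id"].isin(memory_ids) & (rows["n_stimulus_playbacks"] > 1)
    ]
    if len(offending):
        warnings.warn(
            f"{len(offending)} memory-trial responses report more than one "
            "stimulus playback",
            ValidationWarning,
            stacklevel=2,
        )
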