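"""Bin scoring: raw slider distances -> equal-frequency bin scores.

A raw score is the absolute distance |target - final slider| on the 0-100
scale.  Unmoved sliders are scored at the default position, not treated as
missing, but items where more than 30% of respondents left the slider
unmoved are excluded.  Per item, the distance distribution is cut at its
empirical sextiles into six bins of roughly equal occupancy; the smallest
distances earn bin score 6 (best) down to 1 (worst).  Bin boundaries are
persisted so that retest data can be scored against the boundaries
established on the original sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    BinningInfeasibleError,
    DegenerateDistributionError,
    ResponseValidationError,
    SessionConfigError,
)
from .protocol import ResponseMatrix, SessionConfig

__all__ = [
    "DEFAULT_N_BINS",
    "DEFAULT_UNMOVED_THRESHOLD",
    "BinTable",
    "ScoreReport",
    "raw_scores",
    "flag_items",
    "compute_bins",
    "apply_bins",
    "save_bins",
    "load_bins",
    "score_session",
    "distance_summary",
]

DEFAULT_N_BINS = 6
DEFAULT_UNMOVED_THRESHOLD = 0.30


def raw_scores(matrix: ResponseMatrix, session: SessionConfig) -> pd.DataFrame:
    """Absolute slider-target distances, one row per scored response.

    Unmoved sliders are scored at the session's default slider position.
    Returns columns respondent_id, item_id, distance, moved.
    """
    targets = session.targets()
    rows = matrix.table[matrix.table["item_id"].isin(targets)].copy()
    unknown = set(matrix.items) - {it.item_id for it in session.items}
    if unknown:
        raise KeyError(f"responses reference unknown items: {sorted(unknown)}")
    position = np.where(
        rows["moved"], rows["final_slider"], session.default_slider_position
    )
    rows["distance"] = np.abs(rows["item_id"].map(targets).to_numpy() - position)
    return rows[["respondent_id", "item_id", "distance", "moved"]].reset_index(
        drop=True
    )


def flag_items(
    matrix: ResponseMatrix,
    session: SessionConfig,
    threshold: float = DEFAULT_UNMOVED_THRESHOLD,
) -> list[str]:
    """Items whose fraction of unmoved sliders strictly exceeds ``threshold``."""
    scored = {it.item_id for it in session.scored_items()}
    rows = matrix.table[matrix.table["item_id"].isin(scored)]
    unmoved = (~rows["moved"]).groupby(rows["item_id"]).mean()
    return sorted(unmoved.index[unmoved > threshold])


@dataclass(frozen=True)
class BinTable:
    """Per-item interior bin boundaries on the distance scale."""

    version: str
    boundaries: dict[str, tuple[float, ...]]
    excluded: tuple[str, ...] = ()
    n_bins: int = DEFAULT_N_BINS

    def retained_items(self) -> set[str]:
        return set(self.boundaries)


def compute_bins(
    raw: pd.DataFrame,
    session: SessionConfig,
    n_bins: int = DEFAULT_N_BINS,
    excluded: list[str] | None = None,
) -> BinTable:
    """Equal-frequency bin boundaries per item.

    Boundaries sit at the type-1 (inverse empirical CDF) quantiles j/k of
    each item's distance distribution, giving k bins with occupancies equal
    up to ties at a boundary.  Flagged items get no boundaries.
    """
    excluded = sorted(excluded or [])
    probs = np.arange(1, n_bins) / n_bins
    boundaries: dict[str, tuple[float, ...]] = {}
    for item_id, group in raw.groupby("item_id"):
        if item_id in excluded:
            continue
        d = group["distance"].to_numpy()
        if len(d) < n_bins:
            raise BinningInfeasibleError(
                f"item {item_id}: {len(d)} observations cannot fill {n_bins} bins"
            )
        cuts = np.quantile(d, probs, method="inverted_cdf")
        boundaries[item_id] = _dedupe_cuts(cuts, d, item_id, n_bins)
    return BinTable(
        version=session.version,
        boundaries=boundaries,
        excluded=tuple(excluded),
        n_bins=n_bins,
    )


def _dedupe_cuts(
    cuts: np.ndarray, d: np.ndarray, item_id: str, n_bins: int
) -> tuple[float, ...]:
    """Make quantile cuts strictly increasing in the presence of ties.

    A heap of identical distances can pull two quantiles onto the same value;
    the later cut is shifted up to the next distinct observed value, keeping
    exactly ``n_bins`` bins with occupancies equal up to the tie count.
    Fails when the distribution has too few distinct values (e.g. all
    distances identical).
    """
    distinct = np.unique(d)
    out: list[float] = []
    for c in cuts:
        if out and c <= out[-1]:
            above = distinct[distinct > out[-1]]
            # the top boundary must stay below the maximum so no bin is empty
            if above.size < 2:
                raise DegenerateDistributionError(
                    f"item {item_id}: fewer than {n_bins} distinct distance "
                    "values, equal-frequency binning is infeasible"
                )
            c = above[0]
        out.append(float(c))
    return tuple(out)


@dataclass
class ScoreReport:
    """Bin scores per item plus the standard aggregates.

    ``item_scores`` is respondents x items; ``subtask_scores`` holds the
    mean bin score per (dimension, variant) cell; the totals are means over
    the constituent item scores.
    """

    item_scores: pd.DataFrame
    subtask_scores: pd.DataFrame
    match_total: pd.Series
    memory_total: pd.Series | None
    overall: pd.Series = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        out = self.subtask_scores.copy()
        out["match_total"] = self.match_total
        if self.memory_total is not None:
            out["memory_total"] = self.memory_total
        out["overall"] = self.overall
        return out


def _bin_score(distance: np.ndarray, cuts: np.ndarray, n_bins: int) -> np.ndarray:
    # a distance equal to a boundary falls in the lower-distance (better) bin
    return n_bins - np.searchsorted(cuts, distance, side="left")


def apply_bins(
    raw: pd.DataFrame, bins: BinTable, session: SessionConfig
) -> ScoreReport:
    """Convert distances to bin scores (6 best .. 1 worst) and aggregate."""
    if bins.version != session.version:
        raise SessionConfigError(
            f"bin table built for a {bins.version!r} session cannot score a "
            f"{session.version!r} session"
        )
    if (raw["distance"] < 0).any() or (raw["distance"] > 100).any():
        raise ResponseValidationError("distances must lie in [0, 100]")
    retained = bins.retained_items()
    session_ids = {it.item_id for it in session.scored_items()}
    uncovered = (session_ids - set(bins.excluded)) - retained
    if uncovered:
        raise SessionConfigError(
            f"bin table does not cover items: {sorted(uncovered)}"
        )
    rows = raw[raw["item_id"].isin(retained)].copy()
    scores = np.empty(len(rows), dtype=int)
    for item_id, idx in rows.groupby("item_id").indices.items():
        cuts = np.asarray(bins.boundaries[item_id])
        scores[idx] = _bin_score(rows["distance"].to_numpy()[idx], cuts, bins.n_bins)
    rows["score"] = scores

    item_scores = rows.pivot(index="respondent_id", columns="item_id", values="score")

    meta = {it.item_id: it for it in session.scored_items()}
    long = rows.assign(
        block=rows["item_id"].map(lambda i: meta[i].block),
        variant=rows["item_id"].map(lambda i: meta[i].variant),
    )
    cell = long.groupby(["respondent_id", "block", "variant"])["score"].mean()
    subtask = cell.unstack(["block", "variant"])
    subtask.columns = [f"{b}_{v}" for b, v in subtask.columns]
    subtask = subtask.reindex(sorted(subtask.columns), axis=1)

    match_total = (
        long[long["variant"] == "match"].groupby("respondent_id")["score"].mean()
    )
    has_memory = (long["variant"] == "memory").any()
    memory_total = (
        long[long["variant"] == "memory"].groupby("respondent_id")["score"].mean()
        if has_memory
        else None
    )
    overall = long.groupby("respondent_id")["score"].mean()
    return ScoreReport(
        item_scores=item_scores,
        subtask_scores=subtask,
        match_total=match_total,
        memory_total=memory_total,
        overall=overall,
    )


def save_bins(bins: BinTable, path) -> None:
    payload = {
        "version": bins.version,
        "n_bins": bins.n_bins,
        "excluded": list(bins.excluded),
        "boundaries": {k: list(v) for k, v in bins.boundaries.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_bins(path) -> BinTable:
    with open(path) as fh:
        payload = json.load(fh)
    return BinTable(
        version=payload["version"],
        boundaries={k: tuple(v) for k, v in payload["boundaries"].items()},
        excluded=tuple(payload["excluded"]),
        n_bins=payload["n_bins"],
    )


def score_session(
    matrix: ResponseMatrix,
    session: SessionConfig,
    bins: BinTable | None = None,
    unmoved_threshold: float = DEFAULT_UNMOVED_THRESHOLD,
) -> tuple[ScoreReport, BinTable]:
    """End-to-end scoring convenience.

    Without a bin table, flags over-defaulted items, computes boundaries and
    scores in one pass (main-test scoring); with one, scores against the
    supplied boundaries (retest scoring).
    """
    raw = raw_scores(matrix, session)
    if bins is None:
        flagged = flag_items(matrix, session, unmoved_threshold)
        bins = compute_bins(raw, session, excluded=flagged)
    return apply_bins(raw, bins, session), bins


def distance_summary(raw: pd.DataFrame, session: SessionConfig) -> pd.DataFrame:
    """Mean and SD of the raw absolute distance per (dimension, variant).

    The match-versus-memory comparison: larger mean distances on memory
    trials indicate reduced reproduction accuracy from a single playback.
    """
    meta = {it.item_id: it for it in session.scored_items()}
    long = raw.assign(
        block=raw["item_id"].map(lambda i: meta[i].block),
        variant=raw["item_id"].map(lambda i: meta[i].variant),
    )
    out = (
        long.groupby(["block", "variant"])["distance"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "mean_abs_distance", "std": "sd", "count": "n"})
    )
    return out
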