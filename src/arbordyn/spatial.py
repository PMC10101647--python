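"""Spatial clustering statistic for remodeling events.

For each epoch and event kind the *observed* statistic is the mean of all
pairwise 3D Euclidean distances between like-kind events pooled over the
epoch (aligned frame).  The null hypothesis — events land anywhere the
arbor offers — is sampled by redistributing the per-interval event counts
on the arbor present at the matching time point: additions uniformly over
the nodes of the 0.15 μm-resampled arbor, eliminations over its terminal
points.  The randomization is repeated (default 100×) and summarized by

    ratio = observed mean pair distance / mean simulated mean pair distance,

then normalized to each axon's darkness ratio, which corrects both for
arbor size changes and for any systematic placement bias; values below 1
indicate spatial clustering of events beyond what arbor geometry explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .core import Arbor, resample_arbor
from .dynamics import AxonTimeSeries, RemodelingEvent
from .errors import UndefinedStatisticError

__all__ = [
    "EpochSpatialStats",
    "mean_pair_distance",
    "randomize_events",
    "null_mean_pair_distance",
    "clustering_ratios",
]


def mean_pair_distance(events: "list[RemodelingEvent] | np.ndarray") -> float:
    """Mean of all n(n−1)/2 pairwise Euclidean distances (μm).

    Accepts a list of events or a bare (n, 3) coordinate array.

    Raises
    ------
    UndefinedStatisticError
        With fewer than 2 events the statistic has no value (such cells are
        excluded from analysis, not silently zeroed).
    """
    if isinstance(events, np.ndarray):
        coords = events.reshape(-1, 3)
    else:
        coords = np.array([e.coords for e in events], dtype=float).reshape(-1, 3)
    if len(coords) < 2:
        raise UndefinedStatisticError(
            f"mean pair distance undefined for {len(coords)} event(s)"
        )
    return float(pdist(coords).mean())


def randomize_events(
    arbor_at_t: Arbor,
    n_add: int,
    n_elim: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Redistribute event counts at random on one (resampled) arbor.

    ``n_add`` positions are drawn uniformly (with replacement) over all
    nodes; ``n_elim`` positions over the terminal points, without
    replacement when enough terminals exist, with replacement otherwise.
    Returns ``(addition_coords, elimination_coords)`` arrays.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if arbor_at_t.n_nodes == 0:
        raise ValueError("empty arbor")
    nodes = arbor_at_t.xyz
    add = nodes[rng.integers(0, len(nodes), size=n_add)]
    term_idx = [arbor_at_t._index[i] for i in arbor_at_t.terminal_ids]
    terms = nodes[term_idx]
    if n_elim <= len(terms):
        elim = terms[rng.choice(len(terms), size=n_elim, replace=False)]
    else:
        elim = terms[rng.integers(0, len(terms), size=n_elim)]
    return add.reshape(-1, 3), elim.reshape(-1, 3)


class _NullSampler:
    """Caches resampled node clouds / terminal sets per acquisition index."""

    def __init__(self, series: AxonTimeSeries, spacing: float = 0.15):
        self.series = series
        self.spacing = spacing
        self._clouds: dict[int, np.ndarray] = {}
        self._terms: dict[int, np.ndarray] = {}

    def cloud(self, k: int) -> np.ndarray:
        if k not in self._clouds:
            arb = self.series.arbors[k]
            try:
                arb = resample_arbor(arb, self.spacing)
            except ValueError:
                pass  # tiny arbor: raw nodes
            self._clouds[k] = arb.xyz
        return self._clouds[k]

    def terminals(self, k: int) -> np.ndarray:
        if k not in self._terms:
            arb = self.series.arbors[k]
            idx = [arb._index[i] for i in arb.terminal_ids]
            self._terms[k] = arb.xyz[idx]
        return self._terms[k]

    def replicate_means(
        self,
        per_interval: dict[int, int],
        kind: str,
        n_reps: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Replicate mean pair distances for one (epoch, kind) cell.

        ``per_interval`` maps interval index → observed event count.
        Additions in interval i are redistributed on the arbor at
        acquisition i; eliminations on the terminals of the arbor at
        acquisition i−1 (the arbor at *t* for a loss between t and t+10).
        """
        total = sum(per_interval.values())
        if total < 2:
            raise UndefinedStatisticError(
                "fewer than 2 pooled events; null statistic undefined"
            )
        out = np.empty(n_reps)
        items = sorted(per_interval.items())
        for rep in range(n_reps):
            coords = []
            for ival, n in items:
                if n == 0:
                    continue
                if kind == "addition":
                    pool = self.cloud(ival)
                    pick = pool[rng.integers(0, len(pool), size=n)]
                else:
                    pool = self.terminals(ival - 1)
                    if n <= len(pool):
                        pick = pool[rng.choice(len(pool), size=n, replace=False)]
                    else:
                        pick = pool[rng.integers(0, len(pool), size=n)]
                coords.append(pick.reshape(-1, 3))
            out[rep] = pdist(np.vstack(coords)).mean()
        return out


def null_mean_pair_distance(
    series: AxonTimeSeries,
    events: list[RemodelingEvent],
    epoch: str,
    kind: str,
    n_reps: int = 100,
    seed: int | np.random.Generator | None = None,
    spacing: float = 0.15,
) -> np.ndarray:
    """Replicate means of the randomized statistic for one epoch and kind.

    Observed per-interval counts within the epoch are preserved; each
    replicate redistributes them on the matching per-time-point arbor
    geometry, pools over the epoch and takes the mean pair distance.
    Deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_interval: dict[int, int] = {}
    for ev in events:
        if ev.epoch == epoch and ev.kind == kind:
            per_interval[ev.interval_index] = per_interval.get(ev.interval_index, 0) + 1
    return _NullSampler(series, spacing).replicate_means(per_interval, kind, n_reps, rng)


@dataclass
class EpochSpatialStats:
    """Observed vs randomized mean pair distances for one (epoch, kind)."""

    axon_id: str
    epoch: str
    kind: str
    n_events: int
    observed_mean_pd: float  # μm
    simulated_mean_pd: float  # μm, mean over replicates
    replicate_means: np.ndarray = field(repr=False)
    ratio: float  # observed / simulated
    darkness_normalized_ratio: float | None  # None if darkness undefined


def clustering_ratios(
    series: AxonTimeSeries,
    events: list[RemodelingEvent],
    n_reps: int = 100,
    seed: int | None = None,
    spacing: float = 0.15,
) -> tuple[list[EpochSpatialStats], list[str]]:
    """Per-epoch, per-kind observed/randomized ratios for one axon.

    Returns the defined cells plus a list of exclusion messages (cells with
    < 2 pooled events, and kinds whose darkness ratio is undefined — those
    get ``darkness_normalized_ratio`` None, mirroring the exclusion of such
    axons from group analysis rather than silently dropping them).
    """
    rng = np.random.default_rng(seed)
    sampler = _NullSampler(series, spacing)
    epochs = [e.label for e in series.schedule.epochs]
    stats: list[EpochSpatialStats] = []
    exclusions: list[str] = []
    for kind in ("addition", "elimination"):
        cells: dict[str, EpochSpatialStats] = {}
        for epoch in epochs:
            cell_events = [e for e in events if e.epoch == epoch and e.kind == kind]
            per_interval: dict[int, int] = {}
            for ev in cell_events:
                per_interval[ev.interval_index] = (
                    per_interval.get(ev.interval_index, 0) + 1
                )
            if len(cell_events) < 2:
                exclusions.append(
                    f"{series.axon_id}: {kind}/{epoch}: {len(cell_events)} event(s); "
                    "mean pair distance undefined"
                )
                continue
            obs = mean_pair_distance(cell_events)
            reps = sampler.replicate_means(per_interval, kind, n_reps, rng)
            sim = float(reps.mean())
            cells[epoch] = EpochSpatialStats(
                series.axon_id, epoch, kind, len(cell_events), obs, sim, reps,
                obs / sim, None,
            )
        dark = cells.get("dark")
        if dark is None:
            if cells:
                exclusions.append(
                    f"{series.axon_id}: {kind}: no darkness ratio; "
                    "normalization undefined for this kind"
                )
        else:
            for c in cells.values():
                c.darkness_normalized_ratio = c.ratio / dark.ratio
        stats.extend(cells[e] for e in epochs if e in cells)
    return stats, exclusions
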