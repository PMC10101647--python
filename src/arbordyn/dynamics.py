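"""Time-series branch bookkeeping and remodeling-event rates.

Branch identity across time points is consumed as input (a correspondence
table with one stable ``branch_id`` per branch), as maintained by the
tracing software or the synthetic generator.  This module applies the
1.5 μm persistence rule, turns branch births/deaths into addition and
elimination events, and computes per-interval event rates normalized to the
darkness baseline plus the per-epoch window averages.

Timing conventions (acquisitions nominally every 10 min):

* interval ``i`` spans ``(t[i-1], t[i]]``; a missing acquisition simply
  makes one longer (20 min) interval that still counts once;
* a branch first seen at acquisition ``k`` was added in interval ``k``
  (between *t−10 min* and *t*), located at its branch point at ``t``;
* a branch last seen at acquisition ``k`` was eliminated in interval
  ``k+1`` (between *t* and *t+10 min*), located at its terminal point at
  ``t``;
* an interval belongs to the epoch containing its end time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Arbor, Landmarks, fit_rigid
from .errors import InconsistencyError, ScheduleError, UndefinedStatisticError

__all__ = [
    "Epoch",
    "EpochSchedule",
    "AxonTimeSeries",
    "BranchTrack",
    "RemodelingEvent",
    "RateSeries",
    "track_branches",
    "detect_events",
    "classify_fate",
    "rate_series",
    "window_means",
    "MIN_BRANCH_LENGTH_UM",
]

#: Persistence threshold: a branch enters any analysis only if it attained
#: this length (μm) at some point during the imaging session.
MIN_BRANCH_LENGTH_UM = 1.5

EPOCH_ORDER = {"dark": 0, "async": 1, "sync": 2}


@dataclass(frozen=True)
class Epoch:
    label: str  # "dark" | "async" | "sync"
    start_min: float
    end_min: float

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min


@dataclass
class EpochSchedule:
    """Ordered visual-stimulation epochs plus the nominal acquisition interval.

    The canonical protocol is Darkness (1 h) → Asynchronous (1.5–2 h) →
    Synchronous (1.5–2 h) with acquisitions every 10 min.
    """

    epochs: list[Epoch]
    acquisition_interval_min: float = 10.0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ScheduleError("schedule must contain at least one epoch")
        for e in self.epochs:
            if e.label not in EPOCH_ORDER:
                raise ScheduleError(f"unknown epoch label {e.label!r}")
            if e.end_min <= e.start_min:
                raise ScheduleError(f"epoch {e.label} has non-positive duration")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start_min < a.end_min:
                raise ScheduleError("epochs overlap")
            if EPOCH_ORDER[b.label] <= EPOCH_ORDER[a.label]:
                raise ScheduleError(
                    "epochs must run dark before async before sync "
                    f"(found {a.label!r} then {b.label!r})"
                )

    @classmethod
    def das(
        cls,
        dark_min: float = 60.0,
        async_min: float = 120.0,
        sync_min: float = 120.0,
        acquisition_interval_min: float = 10.0,
    ) -> "EpochSchedule":
        """Standard Darkness–Asynchronous–Synchronous protocol."""
        t0, t1 = dark_min, dark_min + async_min
        return cls(
            [
                Epoch("dark", 0.0, dark_min),
                Epoch("async", t0, t1),
                Epoch("sync", t1, t1 + sync_min),
            ],
            acquisition_interval_min,
        )

    @property
    def end_min(self) -> float:
        return self.epochs[-1].end_min

    def epoch_of(self, t_min: float) -> str | None:
        """Label of the epoch owning an interval that *ends* at ``t_min``.

        Uses the half-open convention (start, end]; returns None outside
        every epoch (e.g. an extra trailing time point).
        """
        for e in self.epochs:
            if e.start_min < t_min <= e.end_min:
                return e.label
        return None

    def by_label(self, label: str) -> Epoch:
        for e in self.epochs:
            if e.label == label:
                return e
        raise ScheduleError(f"schedule has no {label!r} epoch")


#: Branch-correspondence table columns expected by :func:`track_branches`.
BRANCH_TABLE_COLUMNS = [
    "time_index", "branch_id", "length_um",
    "bp_x", "bp_y", "bp_z", "tp_x", "tp_y", "tp_z",
]


@dataclass
class AxonTimeSeries:
    """Ordered reconstructions of one axon with times, epochs and identity.

    ``branch_table`` carries the branch correspondence: one row per branch
    per time point with its current length, branch-point (attachment) and
    terminal-point coordinates, all in the same frame as the matching
    arbor.  ``landmarks[k]`` maps frame ``k+1`` onto frame ``k``.
    """

    axon_id: str
    arbors: list[Arbor]
    times_min: list[float]
    schedule: EpochSchedule
    branch_table: pd.DataFrame
    landmarks: list[Landmarks | None] = field(default_factory=list)
    aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.arbors) != len(self.times_min):
            raise ValueError("one acquisition time required per arbor")
        if list(self.times_min) != sorted(self.times_min):
            raise ValueError("acquisition times must increase")
        missing = set(BRANCH_TABLE_COLUMNS) - set(self.branch_table.columns)
        if missing:
            raise InconsistencyError(f"branch table missing columns: {sorted(missing)}")
        if not self.landmarks:
            self.landmarks = [None] * (len(self.arbors) - 1)

    @property
    def n_timepoints(self) -> int:
        return len(self.arbors)

    def align_to_first(self) -> "AxonTimeSeries":
        """Chain consecutive-pair rigid fits so every frame matches frame 0.

        Landmarks for pair (k−1, k) are fitted (Kabsch) and the cumulative
        transform applied to arbor nodes and branch-table coordinates.
        Frames without landmarks are passed through unchanged.
        """
        R_cum = np.eye(3)
        t_cum = np.zeros(3)
        arbors: list[Arbor] = [self.arbors[0]]
        table = self.branch_table.copy()
        for k in range(1, self.n_timepoints):
            lm = self.landmarks[k - 1]
            if lm is not None:
                R, t = fit_rigid(lm.src, lm.dst)
                R_cum, t_cum = R_cum @ R, R_cum @ t + t_cum
            arbors.append(self.arbors[k].transformed(R_cum, t_cum))
            rows = table["time_index"] == k
            for pref in ("bp", "tp"):
                cols = [f"{pref}_x", f"{pref}_y", f"{pref}_z"]
                table.loc[rows, cols] = (
                    table.loc[rows, cols].to_numpy() @ R_cum.T + t_cum
                )
        return AxonTimeSeries(
            self.axon_id, arbors, list(self.times_min), self.schedule,
            table, [None] * (self.n_timepoints - 1), aligned=True,
        )


@dataclass
class BranchTrack:
    """One branch followed across the session."""

    branch_id: int
    first_seen: int  # acquisition index
    last_seen: int
    birth_interval: int | None  # None if present from the first acquisition
    death_interval: int | None  # None if present at the last acquisition
    max_length: float  # μm, maximum attained over the session
    bp_coords: dict[int, np.ndarray]  # acquisition index -> branch point (μm)
    tp_coords: dict[int, np.ndarray]  # acquisition index -> terminal point (μm)
    included: bool  # passed the persistence-length filter

    def present_at(self, time_index: int) -> bool:
        return time_index in self.bp_coords


@dataclass(frozen=True)
class RemodelingEvent:
    """A branch addition or elimination localized in space and time."""

    kind: str  # "addition" | "elimination"
    coords: tuple[float, float, float]  # μm, aligned frame
    interval_index: int
    epoch: str
    branch_id: int


def track_branches(
    series: AxonTimeSeries, min_length: float = MIN_BRANCH_LENGTH_UM
) -> list[BranchTrack]:
    """Build per-branch tracks from the correspondence table.

    A track is ``included`` only if the branch attained ``min_length`` μm at
    some observed time point.  Branches present at intermediate acquisitions
    only get both a birth and a death interval (transient branches).

    Raises
    ------
    InconsistencyError
        If a branch id occurs twice at one time point.
    """
    T = series.n_timepoints
    tracks: list[BranchTrack] = []
    for bid, grp in series.branch_table.groupby("branch_id", sort=True):
        tidx = grp["time_index"].to_numpy()
        if len(np.unique(tidx)) != len(tidx):
            raise InconsistencyError(
                f"branch {bid} appears more than once at a single time point"
            )
        order = np.argsort(tidx)
        grp = grp.iloc[order]
        tidx = tidx[order]
        first, last = int(tidx[0]), int(tidx[-1])
        bp = {
            int(t): row for t, row in zip(tidx, grp[["bp_x", "bp_y", "bp_z"]].to_numpy())
        }
        tp = {
            int(t): row for t, row in zip(tidx, grp[["tp_x", "tp_y", "tp_z"]].to_numpy())
        }
        max_len = float(grp["length_um"].max())
        tracks.append(
            BranchTrack(
                branch_id=int(bid),
                first_seen=first,
                last_seen=last,
                birth_interval=first if first > 0 else None,
                death_interval=last + 1 if last < T - 1 else None,
                max_length=max_len,
                bp_coords=bp,
                tp_coords=tp,
                included=max_len >= min_length,
            )
        )
    return tracks


def detect_events(
    tracks: list[BranchTrack],
    schedule: EpochSchedule,
    times_min: list[float],
    strict: bool = True,
) -> list[RemodelingEvent]:
    """Addition/elimination events of the included (≥ 1.5 μm) tracks.

    An addition is placed at the new branch's branch point at its first
    observed time point; an elimination at the lost branch's terminal point
    at its last observed time point.  Each event carries the epoch of its
    interval (by the interval's end time).

    Raises
    ------
    ScheduleError
        If ``strict`` and an event's interval ends outside every epoch.
    """
    events: list[RemodelingEvent] = []
    for tr in tracks:
        if not tr.included:
            continue
        if tr.birth_interval is not None:
            t_end = times_min[tr.birth_interval]
            epoch = schedule.epoch_of(t_end)
            if epoch is None:
                if strict:
                    raise ScheduleError(
                        f"addition of branch {tr.branch_id} at t={t_end} min "
                        "falls outside every epoch"
                    )
            else:
                c = tr.bp_coords[tr.first_seen]
                events.append(
                    RemodelingEvent(
                        "addition", (float(c[0]), float(c[1]), float(c[2])),
                        tr.birth_interval, epoch, tr.branch_id,
                    )
                )
        if tr.death_interval is not None:
            t_end = times_min[tr.death_interval]
            epoch = schedule.epoch_of(t_end)
            if epoch is None:
                if strict:
                    raise ScheduleError(
                        f"elimination of branch {tr.branch_id} at t={t_end} min "
                        "falls outside every epoch"
                    )
            else:
                c = tr.tp_coords[tr.last_seen]
                events.append(
                    RemodelingEvent(
                        "elimination", (float(c[0]), float(c[1]), float(c[2])),
                        tr.death_interval, epoch, tr.branch_id,
                    )
                )
    events.sort(key=lambda e: (e.interval_index, e.kind, e.branch_id))
    return events


def classify_fate(
    track: BranchTrack, window: tuple[int, int]
) -> str:
    """Fate of a branch over an interval window ``(lo, hi)`` inclusive.

    ``transient`` if both its birth and death intervals fall in the window,
    ``added`` if only the birth does, ``lost`` if only the death does,
    ``stable`` otherwise.
    """
    lo, hi = window
    born = track.birth_interval is not None and lo <= track.birth_interval <= hi
    died = track.death_interval is not None and lo <= track.death_interval <= hi
    if born and died:
        return "transient"
    if born:
        return "added"
    if died:
        return "lost"
    return "stable"


@dataclass
class RateSeries:
    """Per-interval event counts and darkness-normalized rates for one axon.

    ``normalized[kind]`` is ``counts / mean darkness count`` (dimensionless,
    darkness mean 1 by construction) or None when the darkness baseline for
    that kind is zero (``normalization_defined[kind]`` False).
    """

    interval_index: np.ndarray  # (T-1,)
    end_time_min: np.ndarray
    epoch: list[str | None]
    counts: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray | None]
    normalization_defined: dict[str, bool]

    def twenty_min_bins(self, kind: str, bin_min: float = 20.0) -> pd.DataFrame:
        """Mean normalized rate in consecutive time bins (default 20 min).

        Intervals are binned by end time; a longer interval from a missing
        acquisition contributes its single count observation to one bin.
        """
        if self.normalized[kind] is None:
            raise UndefinedStatisticError(
                f"darkness baseline for {kind} is zero; normalized series undefined"
            )
        t = self.end_time_min
        idx = np.ceil(t / bin_min).astype(int) - 1
        df = pd.DataFrame(
            {"bin_start_min": idx * bin_min, "rate": self.normalized[kind]}
        )
        out = df.groupby("bin_start_min", as_index=False)["rate"].mean()
        out["bin_end_min"] = out["bin_start_min"] + bin_min
        return out[["bin_start_min", "bin_end_min", "rate"]]


def rate_series(
    events: list[RemodelingEvent],
    schedule: EpochSchedule,
    times_min: list[float],
) -> RateSeries:
    """Count events per inter-acquisition interval and normalize to darkness.

    The normalized rate of a kind is its interval count divided by that
    kind's mean count per darkness interval; the darkness mean of the
    normalized series is 1 whenever defined.  An all-zero darkness baseline
    flags the kind instead of dividing by zero.
    """
    T = len(times_min)
    ivals = np.arange(1, T)
    end_t = np.asarray(times_min[1:], dtype=float)
    epochs = [schedule.epoch_of(t) for t in end_t]
    counts = {
        kind: np.zeros(T - 1, dtype=float) for kind in ("addition", "elimination")
    }
    for ev in events:
        counts[ev.kind][ev.interval_index - 1] += 1
    dark_mask = np.array([e == "dark" for e in epochs])
    normalized: dict[str, np.ndarray | None] = {}
    defined: dict[str, bool] = {}
    for kind, c in counts.items():
        baseline = c[dark_mask].mean() if dark_mask.any() else 0.0
        if baseline > 0:
            normalized[kind] = c / baseline
            defined[kind] = True
        else:
            normalized[kind] = None
            defined[kind] = False
    return RateSeries(ivals, end_t, epochs, counts, normalized, defined)


def window_means(
    rates: RateSeries,
    schedule: EpochSchedule,
    addition_window_min: float = 60.0,
) -> pd.DataFrame:
    """Per-epoch window averages of the normalized rates.

    Additions are averaged over the first ``addition_window_min`` of each
    stimulation epoch; losses over the last 60 min, or the last 40 min when
    the epoch is shorter than 2 h (the 1.5 h protocol).  Rows are one per
    (epoch, kind); a final pair of rows carries the async/sync ratio per
    kind.  Epochs shorter than the window are truncated with a warning.
    """
    rows = []
    for kind in ("addition", "elimination"):
        if rates.normalized[kind] is None:
            continue
        values = rates.normalized[kind]
        per_epoch: dict[str, float] = {}
        for epoch in schedule.epochs:
            if epoch.label == "dark":
                continue
            if kind == "addition":
                win = (epoch.start_min, epoch.start_min + addition_window_min)
            else:
                loss_win = 60.0 if epoch.duration_min >= 120.0 else 40.0
                win = (epoch.end_min - loss_win, epoch.end_min)
            if win[1] - win[0] > epoch.duration_min:
                warnings.warn(
                    f"epoch {epoch.label} shorter than the averaging window; "
                    "truncating",
                    stacklevel=2,
                )
                win = (epoch.start_min, epoch.end_min)
            mask = (rates.end_time_min > win[0] + 1e-9) & (
                rates.end_time_min <= win[1] + 1e-9
            )
            mean = float(values[mask].mean()) if mask.any() else np.nan
            per_epoch[epoch.label] = mean
            rows.append(
                {
                    "epoch": epoch.label,
                    "kind": kind,
                    "window_start_min": win[0],
                    "window_end_min": win[1],
                    "mean_normalized_rate": mean,
                }
            )
        if "async" in per_epoch and "sync" in per_epoch and per_epoch["sync"]:
            rows.append(
                {
                    "epoch": "async/sync",
                    "kind": kind,
                    "window_start_min": np.nan,
                    "window_end_min": np.nan,
                    "mean_normalized_rate": per_epoch["async"] / per_epoch["sync"],
                }
            )
    return pd.DataFrame(rows)
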