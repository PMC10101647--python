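"""Synthetic arbor-growth generator with ground-truth event logs.

Emulates a time-lapse imaging session of a single axonal arbor under the
Darkness → Asynchronous → Synchronous stimulation protocol (acquisitions
every 10 min): a fixed structural skeleton (trunk plus a few persistent
major branches) carries a churning population of short terminal branches.
Per inter-acquisition interval, new branches appear as a Poisson process
attached at uniformly chosen skeleton nodes and existing branches are
eliminated at a second Poisson rate — uniformly, or preferentially from a
designated subtree when clustering is on.  Branches elongate as jittered
random-walk polylines; a configurable fraction is capped below the 1.5 μm
persistence threshold to exercise the culling rule.  Each emitted time
point is moved by a known rigid motion and accompanied by noisy landmark
pairs, and occasional acquisitions may be dropped, producing one longer
interval, as happens in real sessions.

The generator's bookkeeping (:class:`GroundTruthLog`) is the oracle for the
analysis pipeline: every logged birth/death is visible in the emitted
series, with coordinates in the reference frame of the first time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Arbor, Landmarks, write_swc, read_swc
from .dynamics import AxonTimeSeries, Epoch, EpochSchedule, BRANCH_TABLE_COLUMNS
from .errors import ConfigError, SimulationError

__all__ = [
    "EpochRates",
    "ClusterConfig",
    "GrowthSimConfig",
    "GroundTruthLog",
    "simulate_series",
    "write_series",
    "read_series",
    "make_fixture_suite",
    "make_y_tree",
    "make_binary_tree",
    "random_arbor",
]


@dataclass(frozen=True)
class EpochRates:
    """Per-interval Poisson means for one epoch."""

    add: float  # new branches per 10-min interval
    elim: float  # branch losses per 10-min interval

    def __post_init__(self) -> None:
        if self.add < 0 or self.elim < 0:
            raise ConfigError("rates must be non-negative")


@dataclass(frozen=True)
class ClusterConfig:
    """Spatially clustered elimination: a subtree holding roughly
    ``subtree_fraction`` of terminal points attracts each elimination with
    probability ``p_cluster`` during the listed epochs."""

    subtree_fraction: float = 0.25
    p_cluster: float = 0.8
    epochs: tuple[str, ...] = ("sync",)

    def __post_init__(self) -> None:
        if not 0.0 < self.subtree_fraction < 1.0:
            raise ConfigError("subtree_fraction must lie in (0, 1)")
        if not 0.0 <= self.p_cluster <= 1.0:
            raise ConfigError("p_cluster must lie in [0, 1]")


def _default_rates() -> dict[str, EpochRates]:
    # Stentian/Hebbian preset: exploratory growth under asynchronous input,
    # stabilization with spatially clustered elimination under synchronous.
    return {
        "dark": EpochRates(2.0, 1.5),
        "async": EpochRates(3.5, 2.5),
        "sync": EpochRates(1.2, 1.5),
    }


@dataclass
class GrowthSimConfig:
    """Study conditions for one simulated imaging session.

    Defaults are the canonical protocol: 1 h darkness then 2 h asynchronous
    and 2 h synchronous stimulation at 10-min acquisitions, epoch-dependent
    branch turnover with clustered elimination during synchronous
    stimulation, 0.1 μm landmark noise and a 2% chance of a dropped
    acquisition.
    """

    schedule: EpochSchedule = field(default_factory=EpochSchedule.das)
    rates: dict[str, EpochRates] = field(default_factory=_default_rates)
    clustering: ClusterConfig | None = field(default_factory=ClusterConfig)
    # branch geometry / growth
    elongation_um_per_interval: float = 1.0
    elongation_jitter: float = 0.3  # relative sd of the per-interval increment
    new_branch_initial_um: float = 0.8  # length at first appearance
    branch_min_target_um: float = 1.5
    branch_target_scale_um: float = 2.0  # exponential tail of target lengths
    capped_fraction: float = 0.25  # branches that never reach 1.5 μm
    cap_range_um: tuple[float, float] = (0.5, 1.4)
    polyline_step_um: float = 0.5
    direction_jitter: float = 0.25  # radians-scale wobble per polyline step
    # structural skeleton
    trunk_length_um: float = 60.0
    n_major_branches: int = 4  # one of them is the cluster subtree
    major_length_um: float = 20.0
    n_initial_branches: int = 12
    # session imperfections
    rigid_motion: bool = True
    max_rotation_deg: float = 4.0
    max_translation_um: float = 2.0
    landmark_sigma_um: float = 0.1
    n_landmarks: int = 6
    missing_timepoint_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for label in self.rates:
            if label not in {e.label for e in self.schedule.epochs}:
                raise ConfigError(f"rates given for unscheduled epoch {label!r}")
        for e in self.schedule.epochs:
            if e.label not in self.rates:
                raise ConfigError(f"no rates for epoch {e.label!r}")


@dataclass
class GroundTruthLog:
    """The generator's own event bookkeeping, used as a test oracle.

    ``events`` has one row per true addition/elimination visible in the
    emitted series (columns: branch_id, kind, interval_index, epoch, x, y,
    z, in_cluster_subtree; coordinates in the frame of the first time
    point; the flag marks branches attached inside the designated
    clustered-elimination subtree).
    ``branch_max_length`` records each branch's maximum observed length so
    the 1.5 μm persistence filter can be applied identically on both sides.
    """

    events: pd.DataFrame
    branch_max_length: pd.DataFrame  # branch_id, max_length_um

    def events_filtered(self, min_length: float = 1.5) -> pd.DataFrame:
        keep = set(
            self.branch_max_length.loc[
                self.branch_max_length["max_length_um"] >= min_length, "branch_id"
            ]
        )
        return self.events[self.events["branch_id"].isin(keep)].reset_index(drop=True)


class _SimBranch:
    __slots__ = (
        "bid", "attach", "pts", "length", "target", "direction", "born", "dead",
        "history",
    )

    def __init__(self, bid, attach, pts, length, target, direction, born):
        self.bid = bid
        self.attach = attach  # structural node index
        self.pts = pts  # list of own polyline points
        self.length = length
        self.target = target
        self.direction = direction
        self.born = born  # acquisition step first present
        self.dead: int | None = None  # acquisition step first absent
        self.history: dict[int, tuple[float, np.ndarray]] = {}  # step -> (len, tip)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _grow_polyline(
    branch: _SimBranch, new_length: float, step: float, jitter: float,
    rng: np.random.Generator, attach_pos: np.ndarray,
) -> None:
    """Extend the branch polyline by random-walk steps up to ``new_length``."""
    while branch.length < new_length - 1e-9:
        take = min(step, new_length - branch.length)
        branch.direction = _unit(
            branch.direction + jitter * rng.normal(size=3) * (take / step)
        )
        base = branch.pts[-1] if branch.pts else attach_pos
        branch.pts.append(base + take * branch.direction)
        branch.length += take


def _build_skeleton(cfg: GrowthSimConfig, rng: np.random.Generator):
    """Trunk + major branches; returns (xyz, parent_idx, subtree_mask)."""
    step = 2.0
    xyz: list[np.ndarray] = [np.zeros(3)]
    parent: list[int] = [-1]
    direction = np.array([1.0, 0.0, 0.0])
    n_trunk = max(3, int(round(cfg.trunk_length_um / step)))
    for _ in range(n_trunk):
        direction = _unit(direction + 0.1 * rng.normal(size=3))
        xyz.append(xyz[-1] + step * direction)
        parent.append(len(xyz) - 2)
    trunk_idx = list(range(1, len(xyz)))
    subtree = np.zeros(0, dtype=bool)  # filled below
    n_major = max(1, cfg.n_major_branches)
    # the designated (cluster) major branch is sized so its share of skeleton
    # cable is about the configured subtree fraction
    f = cfg.clustering.subtree_fraction if cfg.clustering else 0.25
    other_len = cfg.major_length_um
    base_cable = cfg.trunk_length_um + (n_major - 1) * other_len
    cluster_len = f * base_cable / max(1e-9, 1.0 - f)
    attach_choices = rng.choice(
        trunk_idx[2:-2], size=n_major, replace=False
    )
    is_subtree: list[bool] = [False] * len(xyz)
    for m in range(n_major):
        length = cluster_len if m == 0 else other_len
        direction = _random_direction(rng)
        # bias away from the trunk axis for visual plausibility
        direction = _unit(direction + np.array([0.2, 0.0, 0.0]))
        prev = int(attach_choices[m])
        remaining = length
        while remaining > 1e-9:
            take = min(step, remaining)
            direction = _unit(direction + 0.1 * rng.normal(size=3))
            xyz.append(xyz[prev] + take * direction)
            parent.append(prev)
            is_subtree.append(m == 0)
            prev = len(xyz) - 1
            remaining -= take
    while len(is_subtree) < len(xyz):
        is_subtree.append(False)
    return np.asarray(xyz), np.asarray(parent), np.asarray(is_subtree, dtype=bool)


def _draw_target(cfg: GrowthSimConfig, rng: np.random.Generator) -> float:
    if rng.uniform() < cfg.capped_fraction:
        return float(rng.uniform(*cfg.cap_range_um))
    return float(cfg.branch_min_target_um + rng.exponential(cfg.branch_target_scale_um))


def _small_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = _random_direction(rng)
    angle = math.radians(rng.uniform(-max_deg, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def simulate_series(
    config: GrowthSimConfig | None = None, axon_id: str = "sim"
) -> tuple[AxonTimeSeries, GroundTruthLog]:
    """Simulate one axon's imaging session.

    Returns the observable :class:`AxonTimeSeries` (arbors and branch table
    in per-time-point *moved* frames, noisy landmarks linking consecutive
    frames) and the :class:`GroundTruthLog` in the frame of time point 0.
    Byte-reproducible for a fixed config seed.

    Raises
    ------
    SimulationError
        If the dynamic branch population goes extinct with no prospect of
        additions (elimination rate positive, all addition rates zero).
    """
    cfg = config or GrowthSimConfig()
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.schedule.acquisition_interval_min
    times = np.arange(0.0, cfg.schedule.end_min + dt / 2, dt)
    T = len(times)
    sk_xyz, sk_parent, sk_subtree = _build_skeleton(cfg, rng)
    S = len(sk_xyz)

    branches: list[_SimBranch] = []
    next_bid = 1

    def new_branch(step_idx: int, initial: float) -> None:
        nonlocal next_bid
        attach = int(rng.integers(1, S))
        br = _SimBranch(
            next_bid, attach, [], 0.0, _draw_target(cfg, rng),
            _random_direction(rng), step_idx,
        )
        next_bid += 1
        _grow_polyline(
            br, min(initial, br.target), cfg.polyline_step_um,
            cfg.direction_jitter, rng, sk_xyz[attach],
        )
        branches.append(br)

    for _ in range(cfg.n_initial_branches):
        new_branch(0, math.inf)  # initial branches start at target length

    def snapshot(step_idx: int) -> None:
        for br in branches:
            if br.dead is None:
                br.history[step_idx] = (br.length, br.pts[-1].copy())

    snapshot(0)
    any_add = any(r.add > 0 for r in cfg.rates.values())
    for s in range(1, T):
        epoch = cfg.schedule.epoch_of(times[s]) or cfg.schedule.epochs[-1].label
        rates = cfg.rates[epoch]
        alive = [b for b in branches if b.dead is None]
        # eliminations between t[s-1] and t[s]
        n_elim = int(rng.poisson(rates.elim))
        clustered = (
            cfg.clustering is not None and epoch in cfg.clustering.epochs
        )
        for _ in range(n_elim):
            if not alive:
                if not any_add and rates.elim > 0:
                    raise SimulationError(
                        "dynamic branch population extinct at "
                        f"t={times[s]:.0f} min with all addition rates zero"
                    )
                break
            pool = alive
            if clustered and rng.uniform() < cfg.clustering.p_cluster:
                # a clustered elimination targets the designated subtree only;
                # if no branch is left there the loss simply does not happen
                pool = [b for b in alive if sk_subtree[b.attach]]
                if not pool:
                    continue
            victim = pool[int(rng.integers(0, len(pool)))]
            victim.dead = s
            alive.remove(victim)
        # additions between t[s-1] and t[s]
        for _ in range(int(rng.poisson(rates.add))):
            new_branch(s, cfg.new_branch_initial_um)
        # elongation of immature surviving branches
        for br in branches:
            if br.dead is None and br.length < br.target - 1e-9:
                delta = cfg.elongation_um_per_interval * max(
                    0.0, 1.0 + cfg.elongation_jitter * rng.normal()
                )
                _grow_polyline(
                    br, min(br.target, br.length + delta), cfg.polyline_step_um,
                    cfg.direction_jitter, rng, sk_xyz[br.attach],
                )
        snapshot(s)

    # occasionally dropped interior acquisitions -> one longer interval
    kept = [0]
    for s in range(1, T - 1):
        if rng.uniform() >= cfg.missing_timepoint_prob:
            kept.append(s)
    kept.append(T - 1)

    # rigid motion per emitted time point (identity for the first)
    motions: list[tuple[np.ndarray, np.ndarray]] = []
    for j, s in enumerate(kept):
        if j == 0 or not cfg.rigid_motion:
            motions.append((np.eye(3), np.zeros(3)))
        else:
            motions.append(
                (
                    _small_rotation(rng, cfg.max_rotation_deg),
                    rng.uniform(-cfg.max_translation_um, cfg.max_translation_um, 3),
                )
            )

    # landmarks: fixed skeleton nodes, observed with noise in each frame
    lm_idx = np.linspace(1, S - 1, cfg.n_landmarks).astype(int)
    lm_true = sk_xyz[lm_idx]
    landmarks: list[Landmarks] = []
    for j in range(1, len(kept)):
        R1, t1 = motions[j]
        R0, t0 = motions[j - 1]
        src = lm_true @ R1.T + t1 + rng.normal(0, cfg.landmark_sigma_um, lm_true.shape)
        dst = lm_true @ R0.T + t0 + rng.normal(0, cfg.landmark_sigma_um, lm_true.shape)
        landmarks.append(Landmarks(src, dst))

    # emitted arbors + branch table (moved frames)
    arbors: list[Arbor] = []
    rows: list[dict] = []
    for j, s in enumerate(kept):
        R, t = motions[j]
        ids = list(range(1, S + 1))
        parents = [-1] + [int(p) + 1 for p in sk_parent[1:]]
        pts = [sk_xyz[i] for i in range(S)]
        nid = S + 1
        for br in sorted(branches, key=lambda b: b.bid):
            if s not in br.history:
                continue
            length, _tip = br.history[s]
            # polyline truncated to the length at this acquisition
            prev = br.attach + 1
            acc = 0.0
            base = sk_xyz[br.attach]
            tip = base
            for p in br.pts:
                seg = float(np.linalg.norm(p - base))
                if acc + seg > length + 1e-9:
                    break
                acc += seg
                ids.append(nid)
                parents.append(prev)
                pts.append(p)
                prev = nid
                nid += 1
                base = p
                tip = p
            bp_m = R @ sk_xyz[br.attach] + t
            tp_m = R @ np.asarray(tip, dtype=float) + t
            rows.append(
                {
                    "time_index": j,
                    "branch_id": br.bid,
                    "length_um": length,
                    "bp_x": bp_m[0], "bp_y": bp_m[1], "bp_z": bp_m[2],
                    "tp_x": tp_m[0], "tp_y": tp_m[1], "tp_z": tp_m[2],
                }
            )
        moved = np.asarray(pts) @ R.T + t
        arbors.append(
            Arbor(ids, parents, moved, radius=np.full(len(ids), 0.3), validate=False)
        )

    table = pd.DataFrame(rows, columns=BRANCH_TABLE_COLUMNS)
    series = AxonTimeSeries(
        axon_id, arbors, [float(times[s]) for s in kept], cfg.schedule,
        table, landmarks,
    )

    # ground-truth log from the kept snapshots (reference frame)
    ev_rows = []
    len_rows = []
    n_obs = len(kept)
    for br in sorted(branches, key=lambda b: b.bid):
        obs = [j for j, s in enumerate(kept) if s in br.history]
        if not obs:
            continue
        first, last = obs[0], obs[-1]
        len_rows.append(
            {
                "branch_id": br.bid,
                "max_length_um": max(br.history[kept[j]][0] for j in obs),
            }
        )
        in_subtree = bool(sk_subtree[br.attach])
        if first > 0:
            t_end = float(times[kept[first]])
            bp = sk_xyz[br.attach]
            ev_rows.append(
                {
                    "branch_id": br.bid, "kind": "addition",
                    "interval_index": first,
                    "epoch": cfg.schedule.epoch_of(t_end),
                    "x": bp[0], "y": bp[1], "z": bp[2],
                    "in_cluster_subtree": in_subtree,
                }
            )
        if last < n_obs - 1:
            t_end = float(times[kept[last + 1]])
            tip = br.history[kept[last]][1]
            ev_rows.append(
                {
                    "branch_id": br.bid, "kind": "elimination",
                    "interval_index": last + 1,
                    "epoch": cfg.schedule.epoch_of(t_end),
                    "x": tip[0], "y": tip[1], "z": tip[2],
                    "in_cluster_subtree": in_subtree,
                }
            )
    events = pd.DataFrame(
        ev_rows,
        columns=[
            "branch_id", "kind", "interval_index", "epoch", "x", "y", "z",
            "in_cluster_subtree",
        ],
    ).sort_values(["interval_index", "kind", "branch_id"], kind="stable").reset_index(
        drop=True
    )
    log = GroundTruthLog(events, pd.DataFrame(len_rows))
    return series, log


# -- disk round trip --------------------------------------------------------------


def write_series(
    series: AxonTimeSeries, out_dir: str | Path, log: GroundTruthLog | None = None
) -> Path:
    """Write a series as SWC files + CSV/YAML metadata (plain text only)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, arbor in enumerate(series.arbors):
        write_swc(arbor, out / f"t{k:03d}.swc")
    series.branch_table.to_csv(out / "branches.csv", index=False, float_format="%.6f")
    lm_rows = []
    for k, lm in enumerate(series.landmarks, start=1):
        if lm is None:
            continue
        for s, d in zip(lm.src, lm.dst):
            lm_rows.append(
                {
                    "t_index": k,
                    "x_src": s[0], "y_src": s[1], "z_src": s[2],
                    "x_dst": d[0], "y_dst": d[1], "z_dst": d[2],
                }
            )
    pd.DataFrame(
        lm_rows,
        columns=["t_index", "x_src", "y_src", "z_src", "x_dst", "y_dst", "z_dst"],
    ).to_csv(out / "landmarks.csv", index=False, float_format="%.6f")
    meta = {
        "axon_id": series.axon_id,
        "times_min": [float(t) for t in series.times_min],
        "acquisition_interval_min": float(series.schedule.acquisition_interval_min),
        "epochs": [
            {"label": e.label, "start_min": float(e.start_min), "end_min": float(e.end_min)}
            for e in series.schedule.epochs
        ],
    }
    (out / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    if log is not None:
        log.events.to_csv(out / "ground_truth_events.csv", index=False,
                          float_format="%.6f")
        log.branch_max_length.to_csv(
            out / "ground_truth_branch_lengths.csv", index=False, float_format="%.6f"
        )
    return out


def read_series(in_dir: str | Path) -> AxonTimeSeries:
    """Read a series written by :func:`write_series`."""
    d = Path(in_dir)
    meta = yaml.safe_load((d / "metadata.yaml").read_text())
    schedule = EpochSchedule(
        [
            __import__("arbordyn.dynamics", fromlist=["Epoch"]).Epoch(
                e["label"], e["start_min"], e["end_min"]
            )
            for e in meta["epochs"]
        ],
        meta["acquisition_interval_min"],
    )
    times = meta["times_min"]
    arbors = [read_swc(d / f"t{k:03d}.swc") for k in range(len(times))]
    table = pd.read_csv(d / "branches.csv")
    lm_df = pd.read_csv(d / "landmarks.csv")
    landmarks: list[Landmarks | None] = []
    for k in range(1, len(times)):
        sub = lm_df[lm_df["t_index"] == k]
        landmarks.append(
            Landmarks(
                sub[["x_src", "y_src", "z_src"]].to_numpy(),
                sub[["x_dst", "y_dst", "z_dst"]].to_numpy(),
            )
            if len(sub)
            else None
        )
    return AxonTimeSeries(meta["axon_id"], arbors, times, schedule, table, landmarks)


# -- canonical small fixtures -----------------------------------------------------


def make_y_tree(stem: float = 10.0, branch: float = 5.0) -> Arbor:
    """Y-shaped arbor: one stem and two terminal branches in the xy plane."""
    h = branch / math.sqrt(2.0)
    ids = [1, 2, 3, 4]
    parents = [-1, 1, 2, 2]
    xyz = np.array(
        [[0, 0, 0], [stem, 0, 0], [stem + h, h, 0], [stem + h, -h, 0]], dtype=float
    )
    return Arbor(ids, parents, xyz)


def make_binary_tree(depth: int = 3, stem: float = 4.0) -> Arbor:
    """Perfect binary tree (2**depth leaves) with a stem, unit edge steps."""
    ids = [1, 2]
    parents = [-1, 1]
    xyz = [np.zeros(3), np.array([stem, 0.0, 0.0])]
    frontier = [(1, np.array([stem, 0.0, 0.0]))]  # (index, position)
    next_id = 3
    for level in range(depth):
        spread = 2.0 ** (depth - level)
        new_frontier = []
        for idx, pos in frontier:
            for sign in (1.0, -1.0):
                p = pos + np.array([2.0, sign * spread, 0.0])
                ids.append(next_id)
                parents.append(ids[idx])
                xyz.append(p)
                new_frontier.append((len(ids) - 1, p))
                next_id += 1
        frontier = new_frontier
    return Arbor(ids, parents, np.asarray(xyz))


def random_arbor(
    seed: int | np.random.Generator,
    n_branches: int = 12,
    step: float = 1.0,
    jitter: float = 0.3,
) -> Arbor:
    """Random tree built by attaching short polyline branches at random nodes.

    Used by property tests; produces branch points (occasionally
    trifurcations) and terminals with generic 3D geometry.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [1]
    parents = [-1]
    xyz = [np.zeros(3)]
    for _ in range(n_branches):
        attach = int(rng.integers(0, len(ids)))
        direction = _random_direction(rng)
        n_steps = int(rng.integers(2, 7))
        prev_idx = attach
        for _ in range(n_steps):
            direction = _unit(direction + jitter * rng.normal(size=3))
            ids.append(len(ids) + 1)
            parents.append(ids[prev_idx])
            xyz.append(xyz[prev_idx] + step * direction)
            prev_idx = len(ids) - 1
    return Arbor(ids, parents, np.asarray(xyz))


def make_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Emit the canonical small fixtures used across the test suite.

    Writes a Y-tree and a perfect binary tree as SWC, plus three small
    simulated series: a uniform-elimination series, a clustered-elimination
    series (all eliminations steered into the designated subtree) and a
    degenerate series whose dynamics reduce to a single transient branch.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    write_swc(make_y_tree(), out / "y_tree.swc")
    paths["y_tree"] = out / "y_tree.swc"
    write_swc(make_binary_tree(3), out / "binary_tree.swc")
    paths["binary_tree"] = out / "binary_tree.swc"
    base = GrowthSimConfig(
        schedule=EpochSchedule.das(30.0, 60.0, 60.0),
        rates={
            "dark": EpochRates(1.5, 1.0),
            "async": EpochRates(1.5, 1.0),
            "sync": EpochRates(1.5, 1.0),
        },
        missing_timepoint_prob=0.0,
        seed=11,
    )
    for name, cfg in {
        "uniform_series": replace(base, clustering=None),
        "clustered_series": replace(
            base,
            clustering=ClusterConfig(0.25, 1.0, ("dark", "async", "sync")),
            seed=12,
        ),
        "single_branch_series": replace(
            base,
            rates={
                "dark": EpochRates(0.0, 0.0),
                "async": EpochRates(0.2, 0.3),
                "sync": EpochRates(0.0, 0.0),
            },
            n_initial_branches=1,
            clustering=None,
            seed=13,
        ),
    }.items():
        series, log = simulate_series(cfg, axon_id=name)
        paths[name] = write_series(series, out / name, log)
    return paths
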