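"""Parallel-cascade-selection adaptive sampling.

Each cycle runs ``n_replicas`` short simulations from the current seeds,
ranks the snapshots (sampled every ``rank_stride``) by the dissociation
coordinate, and reseeds the next cycle from the top-ranked snapshots, until
the coordinate crosses ``cv_threshold`` or ``max_cycles`` is exhausted.  The
full fine-stride trajectory pool is archived with (trial, cycle, replica,
round) provenance for Markov-state-model reuse.

Seeds restart position only: overdamped dynamics carries no velocities, so
"restart with fresh velocities" becomes "restart with a fresh noise stream",
keyed by the (trial, cycle, replica, round) stamp.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model_system import EngineState, LangevinParams, Potential, Segment, propagate
from .structure import SelectionError, Structure


class ArgumentError(ValueError):
    pass


class PreconditionError(ValueError):
    pass


THRESHOLD_REACHED = "threshold_reached"
MAX_CYCLES = "max_cycles"


# ---------------------------------------------------------------------------
# Geometry: inter-center-of-mass distance
# ---------------------------------------------------------------------------


def com_distance(
    structure: Structure,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    masses: np.ndarray | None = None,
) -> float:
    """Distance (Å) between the centers of mass of two atom selections.

    Masses are equal (unweighted centroid) unless ``masses`` is given for
    all atoms.  With a box present, the minimum-image convention is applied
    to the COM separation vector.
    """
    selection_a = np.asarray(selection_a)
    selection_b = np.asarray(selection_b)
    if selection_a.size == 0:
        raise SelectionError("selection_a is empty")
    if selection_b.size == 0:
        raise SelectionError("selection_b is empty")

    def com(sel):
        xyz = structure.coords[sel]
        if masses is None:
            return xyz.mean(axis=0)
        w = np.asarray(masses)[sel]
        return (xyz * w[:, None]).sum(axis=0) / w.sum()

    delta = com(selection_a) - com(selection_b)
    if structure.box is not None:
        delta -= structure.box * np.round(delta / structure.box)
    return float(np.linalg.norm(delta))


# ---------------------------------------------------------------------------
# Configuration and records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CycleConfig:
    """Adaptive-sampling loop parameters.

    Defaults are the desk-scale toy conditions; ``paper_preset()`` returns
    the published all-atom configuration (10 replicas of 100 ps, 1 ps rank
    stride, top 10 reseeded, 50 Å threshold, up to 400 cycles, 5 trials).
    """

    n_replicas: int = 10
    md_length_per_cycle: float = 100.0  # ps
    rank_stride: float = 1.0  # ps
    n_select: int = 10
    cv_threshold: float = 25.0  # Å
    max_cycles: int = 200
    n_trials: int = 5
    selection_cv: str = "distance_from_origin"
    reporting_cv: str = "distance_from_origin"
    extra_rounds: int = 1
    min_pool_segments: int = 1000
    max_extra_rounds: int = 24

    def validate(self) -> None:
        counts = dict(
            n_replicas=self.n_replicas,
            n_select=self.n_select,
            max_cycles=self.max_cycles,
            n_trials=self.n_trials,
        )
        for label, v in counts.items():
            if v < 1:
                raise ArgumentError(f"{label} must be >= 1, got {v}")
        if self.extra_rounds < 0:
            raise ArgumentError("extra_rounds must be >= 0")
        per_replica = self.md_length_per_cycle / self.rank_stride
        if abs(per_replica - round(per_replica)) > 1e-9 or per_replica < 1:
            raise ArgumentError(
                "md_length_per_cycle must be a positive multiple of rank_stride"
            )
        if self.n_select > self.n_replicas * round(per_replica):
            raise ArgumentError("n_select exceeds snapshots per cycle")

    @property
    def snapshots_per_replica(self) -> int:
        return int(round(self.md_length_per_cycle / self.rank_stride))

    @classmethod
    def paper_preset(cls) -> "CycleConfig":
        return cls(cv_threshold=50.0, max_cycles=400, extra_rounds=1)


@dataclass(frozen=True)
class SnapshotRecord:
    """A ranking snapshot with full provenance."""

    trial: int
    cycle: int
    replica: int
    time_in_cycle: float
    cv_selection: float
    cv_reporting: float
    position: np.ndarray
    round: int = 0


def accounting(config: CycleConfig, n_cycles_run: int) -> tuple[float, float]:
    """(lineage_time, aggregate_cost) in ps for ``n_cycles_run`` cycles.

    Lineage time is the contiguous simulated time along the selected path
    (MD length per cycle × cycles); aggregate cost multiplies by the number
    of replicas.  Extra rounds are accounted separately by the archive.
    """
    if n_cycles_run < 0:
        raise ArgumentError("n_cycles_run must be >= 0")
    lineage = config.md_length_per_cycle * n_cycles_run
    return lineage, lineage * config.n_replicas


# ---------------------------------------------------------------------------
# Ranking / selection
# ---------------------------------------------------------------------------


def rank_and_select(snapshots: Sequence[SnapshotRecord], n_select: int) -> list[SnapshotRecord]:
    """The ``n_select`` snapshots with the largest selection coordinate, in
    descending order; ties break toward earlier time then lower replica
    index.  If fewer snapshots exist than requested, the ranked list is
    cycled from the top."""
    if n_select < 1:
        raise ArgumentError(f"n_select must be >= 1, got {n_select}")
    if not snapshots:
        raise ArgumentError("no snapshots to rank")
    ranked = sorted(
        snapshots, key=lambda s: (-s.cv_selection, s.time_in_cycle, s.replica)
    )
    return [ranked[i % len(ranked)] for i in range(n_select)]


# ---------------------------------------------------------------------------
# Toy engine
# ---------------------------------------------------------------------------


class ToyEngine:
    """Adapter between the adaptive-sampling loop and the Langevin toy model.

    ``cv_selection``/``cv_reporting`` map recorded positions to the two
    dissociation coordinates (default for both: distance from the origin,
    the analogue of the inter-COM distance).  Replica noise streams are
    keyed by (base_seed, trial, cycle, replica, round).
    """

    def __init__(
        self,
        potential: Potential,
        params: LangevinParams,
        base_seed: int = 0,
        cv_selection: Callable[[np.ndarray], np.ndarray] | None = None,
        cv_reporting: Callable[[np.ndarray], np.ndarray] | None = None,
    ):
        self.potential = potential
        self.params = params
        self.base_seed = int(base_seed)
        self._cv_sel = cv_selection
        self._cv_rep = cv_reporting

    def segment_cvs(self, segment: Segment) -> tuple[np.ndarray, np.ndarray]:
        sel = self._cv_sel(segment.positions) if self._cv_sel else segment.cv
        rep = self._cv_rep(segment.positions) if self._cv_rep else segment.cv
        return np.asarray(sel, dtype=float), np.asarray(rep, dtype=float)

    def run_segment(
        self, position: np.ndarray, trial: int, cycle: int, replica: int, round: int = 0
    ) -> Segment:
        state = EngineState(position=position, rng_stamp=(trial, cycle, replica))
        seed = [self.base_seed, int(trial), int(cycle), int(replica), int(round)]
        return propagate(self.potential, state, self.params, rng_seed=seed)

    def cv_of(self, position: np.ndarray) -> float:
        pos = np.atleast_2d(np.asarray(position, dtype=float))
        if self._cv_sel:
            return float(np.asarray(self._cv_sel(pos)).ravel()[0])
        return float(np.linalg.norm(pos[0]))


# ---------------------------------------------------------------------------
# Archive
# ---------------------------------------------------------------------------


@dataclass
class PacsArchive:
    """Provenance-stamped trajectory pool plus the selection lineage."""

    config: CycleConfig
    fine_interval_ps: float
    segments: dict[tuple[int, int, int, int], Segment] = field(default_factory=dict)
    snapshots: list[SnapshotRecord] = field(default_factory=list)
    lineage: dict[int, list[list[SnapshotRecord]]] = field(default_factory=dict)
    seeds_used: dict[int, list[list[np.ndarray]]] = field(default_factory=dict)
    termination: dict[int, str] = field(default_factory=dict)
    phase_boundaries: tuple[float, float] | None = None

    @property
    def trials(self) -> list[int]:
        return sorted({key[0] for key in self.segments})

    def n_cycles(self, trial: int) -> int:
        return len(self.lineage.get(trial, []))

    def add_segment(self, trial: int, cycle: int, replica: int,
                    round_index: int, seg: Segment) -> None:
        self.segments[(trial, cycle, replica, round_index)] = seg

    def cv_segments(self, trial: int) -> list[np.ndarray]:
        """Fine-stride CV series, one array per independent segment."""
        return [
            seg.cv
            for (t, _, _, _), seg in sorted(self.segments.items())
            if t == trial
        ]

    def positions(self, trial: int, stride_ps: float) -> np.ndarray:
        """Pooled recorded positions of one trial at ``stride_ps`` spacing."""
        every = max(int(round(stride_ps / self.fine_interval_ps)), 1)
        pools = [
            seg.positions[::every]
            for (t, _, _, _), seg in sorted(self.segments.items())
            if t == trial
        ]
        return np.concatenate(pools)

    def snapshot_table(self) -> pd.DataFrame:
        rows = [
            dict(
                trial=s.trial, cycle=s.cycle, replica=s.replica, round=s.round,
                time_ps=s.time_in_cycle, cv_selection=s.cv_selection,
                cv_reporting=s.cv_reporting,
            )
            for s in self.snapshots
        ]
        return pd.DataFrame(
            rows,
            columns=["trial", "cycle", "replica", "round", "time_ps",
                     "cv_selection", "cv_reporting"],
        )

    def max_cv_by_cycle(self, trial: int) -> np.ndarray:
        df = self.snapshot_table()
        df = df[(df.trial == trial) & (df["round"] == 0)]
        return df.groupby("cycle")["cv_selection"].max().to_numpy()

    def merge(self, other: "PacsArchive") -> None:
        overlap = set(self.segments) & set(other.segments)
        if overlap:
            raise ArgumentError(f"archives overlap on {sorted(overlap)[:3]}...")
        self.segments.update(other.segments)
        self.snapshots.extend(other.snapshots)
        self.lineage.update(other.lineage)
        self.seeds_used.update(other.seeds_used)
        self.termination.update(other.termination)

    # -- persistence (CSV + JSON manifest) ----------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.snapshot_table().to_csv(out / "snapshots.csv", index=False)
        rows = []
        for (trial, cycle, replica, rnd), seg in sorted(self.segments.items()):
            dim = seg.positions.shape[1]
            frame = {
                "trial": trial, "cycle": cycle, "replica": replica, "round": rnd,
                "time_ps": seg.times, "d_angstrom": seg.cv,
            }
            for k, ax in enumerate("xyz"[:dim]):
                frame[ax] = seg.positions[:, k]
            rows.append(pd.DataFrame(frame))
        pd.concat(rows, ignore_index=True).to_csv(out / "segments.csv", index=False)
        meta = {
            "config": asdict(self.config),
            "fine_interval_ps": self.fine_interval_ps,
            "termination": {str(k): v for k, v in self.termination.items()},
            "n_cycles": {str(t): self.n_cycles(t) for t in self.trials},
        }
        (out / "archive.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "PacsArchive":
        src = Path(in_dir)
        meta = json.loads((src / "archive.json").read_text())
        config = CycleConfig(**meta["config"])
        archive = cls(config=config, fine_interval_ps=meta["fine_interval_ps"])
        archive.termination = {int(k): v for k, v in meta["termination"].items()}
        seg_df = pd.read_csv(src / "segments.csv")
        axes = [a for a in "xyz" if a in seg_df.columns]
        for key, grp in seg_df.groupby(["trial", "cycle", "replica", "round"]):
            seg = Segment(
                times=grp["time_ps"].to_numpy(),
                positions=grp[axes].to_numpy(),
                cv=grp["d_angstrom"].to_numpy(),
            )
            archive.segments[tuple(int(k) for k in key)] = seg
        snap_df = pd.read_csv(src / "snapshots.csv")
        for row in snap_df.itertuples():
            archive.snapshots.append(
                SnapshotRecord(
                    trial=int(row.trial), cycle=int(row.cycle),
                    replica=int(row.replica), round=int(row.round),
                    time_in_cycle=float(row.time_ps),
                    cv_selection=float(row.cv_selection),
                    cv_reporting=float(row.cv_reporting),
                    position=np.empty(0),
                )
            )
        # lineage cycle count is recoverable from the metadata
        for t, n in meta["n_cycles"].items():
            archive.lineage[int(t)] = [[] for _ in range(n)]
        return archive


# ---------------------------------------------------------------------------
# The adaptive loop
# ---------------------------------------------------------------------------


def run_pacs_cycle(
    engine: ToyEngine,
    seeds: Sequence[np.ndarray],
    config: CycleConfig,
    trial: int,
    cycle: int,
    archive: PacsArchive,
    round_index: int = 0,
) -> list[SnapshotRecord]:
    """Run one cycle: ``n_replicas`` segments from ``seeds``; archive the
    fine-stride frames; return the rank-stride snapshots."""
    if len(seeds) != config.n_replicas:
        raise ArgumentError(
            f"expected {config.n_replicas} seeds, got {len(seeds)}"
        )
    params = engine.params
    rank_every = int(round(config.rank_stride / params.fine_interval_ps))
    if rank_every < 1 or abs(rank_every * params.fine_interval_ps - config.rank_stride) > 1e-9:
        raise ArgumentError("rank_stride must be a multiple of the fine recording interval")
    snapshots: list[SnapshotRecord] = []
    for replica, seed_pos in enumerate(seeds):
        seg = engine.run_segment(seed_pos, trial, cycle, replica, round_index)
        archive.add_segment(trial, cycle, replica, round_index, seg)
        cv_sel, cv_rep = engine.segment_cvs(seg)
        idx = np.arange(rank_every, len(seg), rank_every)
        for i in idx:
            snapshots.append(
                SnapshotRecord(
                    trial=trial, cycle=cycle, replica=replica, round=round_index,
                    time_in_cycle=float(seg.times[i] - seg.times[0]),
                    cv_selection=float(cv_sel[i]),
                    cv_reporting=float(cv_rep[i]),
                    position=seg.positions[i].copy(),
                )
            )
    archive.snapshots.extend(snapshots)
    return snapshots


def run_pacs_md(
    engine: ToyEngine,
    initial_state: EngineState | np.ndarray,
    config: CycleConfig,
    trial: int = 0,
    selection: str = "top",
) -> PacsArchive:
    """Run the full adaptive-sampling loop for one trial.

    ``selection="top"`` is the cascade-selection rule; ``selection="random"``
    reseeds from uniformly chosen snapshots and serves as the no-selection
    control with an identical per-cycle budget.
    """
    config.validate()
    if selection not in ("top", "random"):
        raise ArgumentError(f"unknown selection rule {selection!r}")
    position = (
        initial_state.position
        if isinstance(initial_state, EngineState)
        else np.asarray(initial_state, dtype=float)
    )
    if engine.cv_of(position) >= config.cv_threshold:
        raise PreconditionError(
            "initial state already beyond cv_threshold "
            f"({engine.cv_of(position):.2f} >= {config.cv_threshold})"
        )
    params_steps = engine.params.timestep * engine.params.n_steps
    if abs(params_steps - config.md_length_per_cycle) > 1e-9:
        raise ArgumentError(
            f"engine runs {params_steps} ps per segment but config expects "
            f"{config.md_length_per_cycle} ps per cycle"
        )

    archive = PacsArchive(config=config, fine_interval_ps=engine.params.fine_interval_ps)
    lineage: list[list[SnapshotRecord]] = []
    seeds_used: list[list[np.ndarray]] = []
    rng_random_sel = np.random.default_rng([engine.base_seed, trial, 0xC0FFEE])
    seeds = [np.array(position, dtype=float) for _ in range(config.n_replicas)]
    termination = MAX_CYCLES
    for cycle in range(1, config.max_cycles + 1):
        seeds_used.append([s.copy() for s in seeds])
        snapshots = run_pacs_cycle(engine, seeds, config, trial, cycle, archive)
        if selection == "top":
            selected = rank_and_select(snapshots, config.n_select)
        else:
            pick = rng_random_sel.integers(0, len(snapshots), size=config.n_select)
            selected = [snapshots[i] for i in pick]
        lineage.append(selected)
        if max(s.cv_selection for s in snapshots) >= config.cv_threshold:
            termination = THRESHOLD_REACHED
            break
        seeds = [s.position.copy() for s in selected]

    archive.lineage[trial] = lineage
    archive.seeds_used[trial] = seeds_used
    archive.termination[trial] = termination

    # Additional replica sets rerun from each cycle's seeds with fresh noise
    # streams, appended to the pool to densify the transition statistics.
    # Trials that dissociate in few cycles get extra sets so every trial
    # reaches a comparable pool size (the number of additional sets varied
    # per trial in the source protocol for the same reason).
    n_rounds = config.extra_rounds
    if config.min_pool_segments:
        base = len(lineage) * config.n_replicas
        needed = -(-config.min_pool_segments // base) - 1  # ceil - 1
        n_rounds = min(max(n_rounds, needed), config.max_extra_rounds)
    for rnd in range(1, n_rounds + 1):
        for cycle_index, cycle_seeds in enumerate(seeds_used, start=1):
            run_pacs_cycle(engine, cycle_seeds, config, trial, cycle_index,
                           archive, round_index=rnd)
    return archive


def run_trials(
    engine: ToyEngine,
    initial_position: np.ndarray,
    config: CycleConfig,
    selection: str = "top",
) -> PacsArchive:
    """Run ``config.n_trials`` independent trials and merge the archives."""
    combined: PacsArchive | None = None
    for trial in range(config.n_trials):
        archive = run_pacs_md(engine, initial_position, config, trial=trial,
                              selection=selection)
        if combined is None:
            combined = archive
        else:
            combined.merge(archive)
    assert combined is not None
    return combined
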