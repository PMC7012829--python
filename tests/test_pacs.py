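"""Adaptive-sampling loop: COM distances, ranking, cycles, accounting."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pacsfe.model_system import LangevinParams, PotentialSpec, make_potential
from pacsfe.pacs import (
    ArgumentError,
    CycleConfig,
    PacsArchive,
    PreconditionError,
    SnapshotRecord,
    ToyEngine,
    accounting,
    com_distance,
    rank_and_select,
    run_pacs_cycle,
    run_pacs_md,
)
from pacsfe.structure import SelectionError, Structure


def _structure(coords, chains=None, box=None):
    n = len(coords)
    return Structure(
        names=np.full(n, "C"),
        elements=np.full(n, "C"),
        resnames=np.full(n, "BEA"),
        resids=np.arange(1, n + 1),
        chains=np.full(n, "A") if chains is None else np.asarray(chains),
        coords=np.asarray(coords, dtype=float),
        box=box,
    )


class TestComDistance:
    def test_three_four_five_triangle(self):
        s = _structure([[0, 0, 0], [3, 4, 0]])
        assert com_distance(s, [0], [1]) == pytest.approx(5.0)

    def test_identical_selections_give_zero(self):
        s = _structure([[1, 2, 3], [4, 5, 6]])
        assert com_distance(s, [0, 1], [0, 1]) == 0.0

    def test_square_centroid_equals_center(self):
        square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0.5, 0.5, 0]]
        s = _structure(square)
        assert com_distance(s, [0, 1, 2, 3], [4]) == pytest.approx(0.0, abs=1e-12)

    def test_empty_selection_raises(self):
        s = _structure([[0, 0, 0]])
        with pytest.raises(SelectionError, match="selection_a"):
            com_distance(s, np.array([], dtype=int), [0])

    def test_minimum_image_under_box(self):
        s = _structure([[1, 1, 1], [9, 1, 1]], box=np.array([10.0, 10.0, 10.0]))
        assert com_distance(s, [0], [1]) == pytest.approx(2.0)

    def test_truncated_selection_changes_cv(self):
        # excluding a displaced flexible segment moves the COM: the
        # selection CV and the reporting (full) CV must disagree, and agree
        # again when nothing is excluded
        rigid = [[0, 0, 0], [2, 0, 0]]
        flexible = [[0, 0, 40], [2, 0, 40]]
        partner = [[20, 0, 0]]
        s = _structure(rigid + flexible + partner)
        cv_selection = com_distance(s, [0, 1], [4])
        cv_reporting = com_distance(s, [0, 1, 2, 3], [4])
        assert cv_selection != pytest.approx(cv_reporting)
        assert com_distance(s, [0, 1], [4]) == pytest.approx(
            com_distance(s, [0, 1], [4])
        )


class TestRankAndSelect:
    def snap(self, cv, time=1.0, replica=0):
        return SnapshotRecord(
            trial=0, cycle=1, replica=replica, time_in_cycle=time,
            cv_selection=cv, cv_reporting=cv, position=np.zeros(3),
        )

    def test_selects_largest_descending(self):
        snaps = [self.snap(9.8), self.snap(15.1), self.snap(12.3)]
        out = rank_and_select(snaps, 2)
        assert [s.cv_selection for s in out] == [15.1, 12.3]

    def test_all_snapshots_descending(self):
        snaps = [self.snap(cv) for cv in (1.0, 3.0, 2.0)]
        out = rank_and_select(snaps, 3)
        assert [s.cv_selection for s in out] == [3.0, 2.0, 1.0]

    def test_tie_break_earlier_time_first(self):
        a = self.snap(10.0, time=1.0, replica=5)
        b = self.snap(10.0, time=2.0, replica=0)
        assert rank_and_select([b, a], 1)[0] is a

    def test_cycles_through_when_short(self):
        snaps = [self.snap(2.0), self.snap(1.0)]
        out = rank_and_select(snaps, 5)
        assert [s.cv_selection for s in out] == [2.0, 1.0, 2.0, 1.0, 2.0]

    def test_invalid_n_select(self):
        with pytest.raises(ArgumentError):
            rank_and_select([self.snap(1.0)], 0)

    @given(
        cvs=st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1,
            max_size=30,
        ),
        n=st.integers(min_value=1, max_value=10),
    )
    def test_matches_exhaustive_sort_oracle(self, cvs, n):
        snaps = [self.snap(cv, time=i, replica=i) for i, cv in enumerate(cvs)]
        got = [s.cv_selection for s in rank_and_select(snaps, n)]
        ranked = sorted(cvs, reverse=True)
        expected = [ranked[i % len(ranked)] for i in range(n)]
        assert got == expected


@pytest.fixture(scope="module")
def engine():
    pot = make_potential(PotentialSpec())
    return ToyEngine(pot, LangevinParams(n_steps=100_000), base_seed=9)


class TestCycles:
    def test_snapshot_count_ten_replicas_hundred_ps(self, engine):
        # 10 replicas x 100 ps sampled every 1 ps -> 1000 ranking snapshots
        config = CycleConfig()
        archive = PacsArchive(config=config, fine_interval_ps=engine.params.fine_interval_ps)
        seeds = [np.zeros(3)] * 10
        snaps = run_pacs_cycle(engine, seeds, config, trial=0, cycle=1, archive=archive)
        assert len(snaps) == 1000

    def test_single_snapshot_when_stride_is_run_length(self):
        pot = make_potential(PotentialSpec())
        eng = ToyEngine(pot, LangevinParams(n_steps=2000, record_stride_fine=1000), base_seed=0)
        config = CycleConfig(n_replicas=1, md_length_per_cycle=2.0, rank_stride=2.0, n_select=1)
        archive = PacsArchive(config=config, fine_interval_ps=eng.params.fine_interval_ps)
        snaps = run_pacs_cycle(eng, [np.zeros(3)], config, 0, 1, archive)
        assert len(snaps) == 1

    def test_cycle_determinism(self, engine):
        config = CycleConfig(n_replicas=2, n_select=2)
        a1 = PacsArchive(config=config, fine_interval_ps=engine.params.fine_interval_ps)
        a2 = PacsArchive(config=config, fine_interval_ps=engine.params.fine_interval_ps)
        seeds = [np.zeros(3), np.ones(3)]
        s1 = run_pacs_cycle(engine, seeds, config, 0, 1, a1)
        s2 = run_pacs_cycle(engine, seeds, config, 0, 1, a2)
        assert [s.cv_selection for s in s1] == [s.cv_selection for s in s2]


class TestRunPacsMd:
    def small_setup(self, seed=0, **cfg_kw):
        pot = make_potential(PotentialSpec())
        params = LangevinParams(n_steps=10_000)  # 10 ps cycles
        cfg = dict(
            n_replicas=3, md_length_per_cycle=10.0, rank_stride=1.0, n_select=3,
            cv_threshold=25.0, max_cycles=3, extra_rounds=0, min_pool_segments=0,
        )
        cfg.update(cfg_kw)
        return ToyEngine(pot, params, base_seed=seed), CycleConfig(**cfg)

    def test_initial_state_beyond_threshold_rejected(self):
        engine, config = self.small_setup()
        with pytest.raises(PreconditionError):
            run_pacs_md(engine, np.array([29.0, 0, 0]), config)

    def test_unreachable_threshold_terminates_at_max_cycles(self):
        engine, config = self.small_setup(cv_threshold=28.0, max_cycles=3)
        archive = run_pacs_md(engine, np.zeros(3), config, trial=0)
        assert archive.termination[0] == "max_cycles"
        assert archive.n_cycles(0) == 3

    def test_archive_frame_conservation(self):
        engine, config = self.small_setup(cv_threshold=28.0, max_cycles=2)
        archive = run_pacs_md(engine, np.zeros(3), config, trial=0)
        frames_per_segment = (
            engine.params.n_steps // engine.params.record_stride_fine + 1
        )
        expected = archive.n_cycles(0) * config.n_replicas * frames_per_segment
        total = sum(len(seg) for seg in archive.segments.values())
        assert total == expected

    def test_running_max_cv_non_decreasing(self):
        engine, config = self.small_setup(cv_threshold=28.0, max_cycles=4)
        archive = run_pacs_md(engine, np.zeros(3), config, trial=0)
        per_cycle_max = archive.max_cv_by_cycle(0)
        running = np.maximum.accumulate(per_cycle_max)
        assert np.all(np.diff(running) >= 0)

    def test_selection_accelerates_deep_well_escape(self):
        # cascade selection must dissociate a 12 kT well that plain
        # (random-reseeding) runs of identical budget never escape
        spec = PotentialSpec(
            well_depth_0=12.0, pressure_coefficient=0.0, bound_radius=3.0,
            stiffness=5.0, wall_radius=12.0,
        )
        params = LangevinParams(n_steps=20_000)
        config = CycleConfig(
            n_replicas=4, md_length_per_cycle=20.0, rank_stride=0.2, n_select=4,
            cv_threshold=10.0, max_cycles=40, extra_rounds=0, min_pool_segments=0,
        )
        results = {}
        for selection in ("top", "random"):
            cycles = []
            for s in range(5):
                eng = ToyEngine(make_potential(spec), params, base_seed=100 + s)
                arc = run_pacs_md(eng, np.zeros(3), config, trial=0, selection=selection)
                reached = arc.termination[0] == "threshold_reached"
                cycles.append(arc.n_cycles(0) if reached else config.max_cycles + 1)
            results[selection] = cycles
        for c_top in results["top"]:
            assert c_top <= config.max_cycles  # every selected run dissociates
        assert np.median(results["top"]) < np.median(results["random"])


class TestAccounting:
    def test_paper_scale_lineage_and_aggregate(self):
        config = CycleConfig.paper_preset()
        lineage_ps, aggregate_ps = accounting(config, 400)
        assert lineage_ps / 1000.0 == pytest.approx(40.0)  # ns
        assert aggregate_ps / 1000.0 == pytest.approx(400.0)  # ns

    def test_zero_cycles(self):
        assert accounting(CycleConfig(), 0) == (0.0, 0.0)

    def test_negative_cycles_rejected(self):
        with pytest.raises(ArgumentError):
            accounting(CycleConfig(), -1)
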