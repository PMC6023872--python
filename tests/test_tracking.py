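"""Trajectory linking, FRET proximity, density maps, NeNA precision."""

import numpy as np
import pandas as pd
import pytest

from fretblink import synthetic_data as sd
from fretblink import tracking as tk


def loc_table(rows):
    return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "intensity_adu"])


def static_molecule(x, y, frames, intensity=300.0):
    return [(f, x, y, intensity) for f in frames]


class TestLink:
    def test_single_static_molecule(self):
        locs = loc_table(static_molecule(1000.0, 2000.0, range(10)))
        trajs = tk.link(locs)
        assert len(trajs) == 1
        assert trajs[0].n_localizations == 10

    def test_distant_molecules_never_merge(self):
        locs = loc_table(
            static_molecule(1000.0, 1000.0, range(8))
            + static_molecule(1500.0, 1000.0, range(8))  # 500 nm > 100 nm gate
        )
        trajs = tk.link(locs)
        assert len(trajs) == 2
        assert all(t.n_localizations == 8 for t in trajs)

    def test_single_frame_gap_bridged(self):
        frames = [0, 1, 2, 4, 5]  # frame 3 missed
        locs = loc_table(static_molecule(500.0, 500.0, frames))
        trajs = tk.link(locs)
        assert len(trajs) == 1
        assert trajs[0].n_localizations == 5
        assert trajs[0].track_length == pytest.approx(6 * 0.5)

    def test_two_frame_gap_splits(self):
        locs = loc_table(static_molecule(500.0, 500.0, [0, 1, 2, 6, 7, 8]))
        assert len(tk.link(locs)) == 2

    def test_short_tracks_discarded(self):
        locs = loc_table(static_molecule(500.0, 500.0, [0, 1]))
        assert tk.link(locs) == []

    def test_row_order_invariance(self):
        locs, _ = sd.simulate_trajectories(
            n_tracks=10, confined_sd=20.0, precision_sd=10.0, detection_p=0.9,
            seed=3, n_frames_per_track=20, min_separation_nm=600.0,
        )
        shuffled = locs.sample(frac=1.0, random_state=7).reset_index(drop=True)
        as_sets = lambda trajs: {
            tuple(map(tuple, np.column_stack([t.frames, t.x, t.y]))) for t in trajs
        }
        assert as_sets(tk.link(locs)) == as_sets(tk.link(shuffled))

    def test_outputs_satisfy_trajectory_invariants(self):
        locs, _ = sd.simulate_trajectories(
            n_tracks=15, confined_sd=25.0, precision_sd=10.0, detection_p=0.85,
            seed=5, n_frames_per_track=25, min_separation_nm=500.0,
        )
        for t in tk.link(locs):
            t.check(max_disp=100.0, max_gap=1, min_locs=3)

    def test_matches_exhaustive_oracle_on_small_scenes(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            locs, _ = sd.simulate_trajectories(
                n_tracks=int(rng.integers(2, 7)),
                confined_sd=25.0,
                precision_sd=10.0,
                detection_p=0.85,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_frames_per_track=20,
                field_nm=4000.0,
                min_separation_nm=300.0,
            )
            got = tk.link(locs)
            expected = oracle_link(locs)
            assert as_canonical(got) == as_canonical(expected)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            tk.link(pd.DataFrame({"frame": [0], "x_nm": [0.0]}))


def as_canonical(trajs):
    out = set()
    for t in trajs:
        if isinstance(t, tk.Trajectory):
            rows = np.column_stack([t.frames, t.x, t.y])
        else:
            rows = np.asarray(t, dtype=float)
        out.add(tuple(map(tuple, np.round(rows, 6))))
    return out


def oracle_link(locs, max_disp=100.0, max_gap=1, min_locs=3):
    """Independent plain-loop linker with the same gate/gap/tie rules:
    candidate (track, localization) pairs processed in ascending distance,
    ties by track id then sorted localization order."""
    df = pd.DataFrame(locs).sort_values(
        ["frame", "x_nm", "y_nm", "intensity_adu"], kind="mergesort"
    )
    tracks = []  # each: list of (frame, x, y)
    last = []  # (frame, x, y) per track
    for f in range(int(df.frame.min()), int(df.frame.max()) + 1):
        pts = df[df.frame == f][["x_nm", "y_nm"]].to_numpy().tolist()
        pairs = []
        for ti, (lf, lx, ly) in enumerate(last):
            if not 1 <= f - lf <= max_gap + 1:
                continue
            for ci, (x, y) in enumerate(pts):
                d = np.hypot(x - lx, y - ly)
                if d <= max_disp:
                    pairs.append((d, ti, ci))
        pairs.sort()
        used_t, used_c = set(), set()
        for d, ti, ci in pairs:
            if ti in used_t or ci in used_c:
                continue
            used_t.add(ti)
            used_c.add(ci)
            x, y = pts[ci]
            tracks[ti].append((f, x, y))
            last[ti] = (f, x, y)
        for ci, (x, y) in enumerate(pts):
            if ci not in used_c:
                tracks.append([(f, x, y)])
                last.append((f, x, y))
    return [t for t in tracks if len(t) >= min_locs]


class TestTrackLengthCutoff:
    def test_constant_lengths(self):
        with pytest.warns(UserWarning):
            assert tk.track_length_cutoff([5.0] * 10) == 5.0

    def test_uniform_lengths(self):
        rng = np.random.default_rng(0)
        lengths = rng.uniform(0, 10, size=20000)
        assert tk.track_length_cutoff(lengths) == pytest.approx(9.9, abs=0.05)

    def test_validation(self):
        with pytest.raises(ValueError):
            tk.track_length_cutoff([])
        with pytest.raises(ValueError):
            tk.track_length_cutoff([1.0] * 200, quantile=1.5)


class TestTrajectoryFret:
    def make_traj(self, intensities):
        n = len(intensities)
        return tk.Trajectory(0, np.arange(n), np.zeros(n), np.zeros(n),
                             np.asarray(intensities, float))

    def test_reference_intensity_gives_zero(self):
        t = self.make_traj([300.0] * 5)
        assert tk.trajectory_fret(t, 300.0) == 0.0

    def test_half_intensity_gives_half(self):
        t = self.make_traj([150.0] * 5)
        assert tk.trajectory_fret(t, 300.0) == pytest.approx(0.5)

    def test_first_and_last_frames_ignored(self):
        t = self.make_traj([10.0, 150.0, 150.0, 150.0, 10.0])
        assert t.mean_intensity == pytest.approx(150.0)

    def test_validation(self):
        t = self.make_traj([300.0] * 5)
        with pytest.raises(ValueError):
            tk.trajectory_fret(t, 0.0)

    def test_donor_only_cohort_mean_near_zero(self):
        locs, _ = sd.simulate_trajectories(
            n_tracks=40, confined_sd=15.0, precision_sd=10.0, detection_p=1.0,
            seed=21, n_frames_per_track=30, intensity_mean=300.0,
            intensity_cv=0.1, min_separation_nm=1200.0, field_nm=30000.0,
        )
        trajs = tk.link(locs)
        ref = np.mean([t.mean_intensity for t in trajs])
        effs = [tk.trajectory_fret(t, ref) for t in trajs]
        assert abs(np.mean(effs)) < 0.02


class TestDensityMap:
    def test_single_bin_conservation(self):
        trajs = [
            tk.Trajectory(i, np.arange(4), np.full(4, 100.0 + i),
                          np.full(4, 100.0), np.full(4, 300.0))
            for i in range(7)
        ]
        dmap = tk.density_map(trajs, bin_width=312.0)
        assert dmap.n_assigned == 7
        assert dmap.counts.sum() == 7
        assert (dmap.counts > 0).sum() == 1

    def test_two_clusters_classified_by_cutoff(self):
        short = [
            tk.Trajectory(i, np.arange(3), np.full(3, 100.0), np.full(3, 100.0),
                          np.full(3, 300.0), exposure=0.5)
            for i in range(5)
        ]
        long = [
            tk.Trajectory(5 + i, np.arange(40), np.full(40, 5000.0),
                          np.full(40, 5000.0), np.full(40, 300.0), exposure=0.5)
            for i in range(5)
        ]
        dmap = tk.density_map(short + long, bin_width=312.0, cutoff=12.0)
        assert dmap.counts.sum() == 10
        lens = dmap.mean_track_length[dmap.counts > 0]
        above = dmap.above_cutoff[dmap.counts > 0]
        assert set(np.round(lens, 3)) == {1.5, 20.0}
        assert list(above) == [cl > 12.0 for cl in lens]

    def test_empty_input(self):
        dmap = tk.density_map([])
        assert dmap.n_assigned == 0


class TestNnPrecision:
    def static_cohort(self, precision, n=60, frames=25, seed=2):
        locs, _ = sd.simulate_trajectories(
            n_tracks=n, confined_sd=0.0, precision_sd=precision, detection_p=1.0,
            seed=seed, n_frames_per_track=frames, min_separation_nm=1500.0,
            field_nm=40000.0,
        )
        return locs

    def test_recovers_15_nm(self):
        sigma = tk.nn_precision(self.static_cohort(15.0))
        assert sigma == pytest.approx(15.0, abs=2.0)

    def test_zero_jitter_degenerates_to_zero(self):
        assert tk.nn_precision(self.static_cohort(0.0)) == 0.0

    def test_precision_ordering_recovered(self):
        s1 = tk.nn_precision(self.static_cohort(11.9, seed=5))
        s2 = tk.nn_precision(self.static_cohort(13.3, seed=6))
        assert s2 > s1

    def test_too_few_pairs(self):
        locs = loc_table(static_molecule(0.0, 0.0, range(3)))
        with pytest.raises(tk.PrecisionError):
            tk.nn_precision(locs)
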