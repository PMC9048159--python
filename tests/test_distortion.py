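"""Marker detection, distortion shifts, shell means and Eq.-style longitudinal stats."""

import numpy as np
import pandas as pd
import pytest

from petmr_qa.core import MarkerSet, QAError, RigidTransform
from petmr_qa.distortion import (
    SHELL_LABELS,
    DistortionResult,
    ReferenceGrid,
    check_tolerance,
    compute_distortion,
    detect_markers,
    longitudinal_stats,
)
from petmr_qa.phantoms import GridPhantomSpec, gen_grid_phantom, _add_blob

SMALL = dict(extent=(5, 5, 4), grid_spacing=14.0)


def _match_errors(truth, detected):
    ids_t, pts_t = truth.as_arrays()
    tmap = dict(zip(ids_t.tolist(), pts_t))
    ids_m, pts_m = detected.as_arrays()
    return np.array([np.linalg.norm(tmap[i] - p) for i, p in zip(ids_m.tolist(), pts_m)])


class TestDetectMarkers:
    def test_zero_displacement_all_found_at_nominal(self):
        spec = GridPhantomSpec(**SMALL, seed=3)
        vol, truth = gen_grid_phantom(spec)
        ms = detect_markers(vol, spec.reference_grid())
        assert len(ms) == len(truth)
        assert not ms.missing
        assert _match_errors(truth, ms).max() < 0.1

    def test_deleted_marker_reported_missing(self):
        spec = GridPhantomSpec(**SMALL, seed=3)
        grid = spec.reference_grid()
        vol, _ = gen_grid_phantom(spec)
        # erase the blob of marker 0 from the image
        vox = vol.voxels
        idx = np.round(vol.world_to_voxel(grid.positions[0])).astype(int)
        vox[tuple(slice(max(0, i - 6), i + 7) for i in idx)] = 0.0
        ms = detect_markers(vol, grid)
        assert 0 in ms.missing
        assert 0 not in ms.positions

    def test_duplicate_candidates_keep_brighter(self):
        spec = GridPhantomSpec(**SMALL, seed=3)
        vol, _ = gen_grid_phantom(spec)
        grid = spec.reference_grid()
        # add a dimmer decoy blob 6.5 mm from marker 0 (both candidates map
        # to id 0; the brighter original must win)
        decoy = grid.positions[0] + np.array([6.5, 0.0, 0.0])
        _add_blob(
            vol.voxels, np.asarray(vol.origin), np.asarray(vol.spacing), decoy, 1.25, 600.0
        )
        ms = detect_markers(vol, grid)
        assert ms.spurious == 1
        # the kept candidate is the brighter blob: much nearer the true
        # marker than the decoy (its centroid is mildly contaminated by
        # the decoy tail, which is expected for overlapping blobs)
        d_marker = np.linalg.norm(ms.positions[0] - grid.positions[0])
        d_decoy = np.linalg.norm(ms.positions[0] - decoy)
        assert d_marker < 2.0
        assert d_decoy > 2.0 * d_marker

    def test_wrong_phantom_hard_failure(self):
        spec = GridPhantomSpec(**SMALL, seed=3)
        vol, _ = gen_grid_phantom(spec)
        big_grid = ReferenceGrid.regular((11, 11, 10), 14.0)
        with pytest.raises(QAError, match="markers detected"):
            detect_markers(vol, big_grid)


class TestComputeDistortion:
    def test_identity_measurements_give_zero_shifts(self):
        grid = ReferenceGrid.regular((3, 3, 3), 20.0)
        ms = MarkerSet(positions={i: p.copy() for i, p in grid.positions.items()})
        res = compute_distortion(ms, grid, setup=RigidTransform())
        assert res.table["shift_mm"].max() == pytest.approx(0.0, abs=1e-12)
        assert res.shell_means["d<10cm"] == pytest.approx(0.0, abs=1e-12)

    def test_three_four_zero_displacement_gives_shift_five(self):
        grid = ReferenceGrid.regular((3, 3, 3), 20.0)
        pos = {i: p.copy() for i, p in grid.positions.items()}
        pos[13] = pos[13] + np.array([3.0, 4.0, 0.0])
        res = compute_distortion(MarkerSet(positions=pos), grid, setup=RigidTransform())
        assert res.table.set_index("id").loc[13, "shift_mm"] == pytest.approx(5.0)

    def test_shell_partition_is_exhaustive_and_disjoint(self, rng):
        grid = ReferenceGrid.regular((7, 7, 7), 60.0)  # spans all shells
        pos = {i: p + rng.normal(0, 0.5, 3) for i, p in grid.positions.items()}
        res = compute_distortion(MarkerSet(positions=pos), grid, setup=RigidTransform())
        assert sum(res.shell_counts.values()) == len(pos)
        assert set(res.table["shell"]).issubset(set(SHELL_LABELS))

    def test_invariance_under_phantom_rigid_motion(self, rng):
        # distortion must not change when the phantom is moved and the
        # setup transform re-estimated
        spec = GridPhantomSpec(**SMALL, seed=5)
        vol, _ = gen_grid_phantom(spec)
        grid = spec.reference_grid()
        base = compute_distortion(detect_markers(vol, grid), grid)
        tab = base.table
        for _ in range(3):
            motion = RigidTransform(*rng.uniform(-5, 5, 3), *rng.uniform(-2, 2, 3))
            moved = MarkerSet(
                positions={
                    int(i): motion.apply(np.array([x, y, z]))
                    for i, x, y, z in zip(tab["id"], tab["x"], tab["y"], tab["z"])
                }
            )
            res = compute_distortion(moved, grid)
            merged = base.table.merge(res.table, on="id", suffixes=("_a", "_b"))
            assert np.abs(merged["shift_mm_a"] - merged["shift_mm_b"]).max() < 0.05

    def test_empty_marker_set_fails(self):
        grid = ReferenceGrid.regular((3, 3, 3), 20.0)
        with pytest.raises(QAError):
            compute_distortion(MarkerSet(), grid, setup=RigidTransform())


def _fake_session(shifts: dict[int, float], session: str = "") -> DistortionResult:
    table = pd.DataFrame(
        {
            "id": list(shifts),
            "x": 0.0,
            "y": 0.0,
            "z": 0.0,
            "shift_mm": list(shifts.values()),
            "d_iso_mm": 0.0,
            "shell": SHELL_LABELS[0],
        }
    )
    return DistortionResult(
        table=table,
        shell_means={},
        shell_counts={},
        sequence="3D",
        setup_transform=RigidTransform(),
        session=session,
    )


class TestLongitudinalStats:
    def test_identical_sessions_have_zero_sd_and_range(self):
        sessions = [_fake_session({1: 0.5, 2: 1.0})] * 3
        res = longitudinal_stats(sessions)
        assert res.sigma_bar == 0.0
        assert res.mean_range == 0.0

    def test_hand_oracle_two_markers_three_sessions(self):
        # marker 1: {1.0, 1.2, 1.4} -> sd 0.2, range 0.4
        # marker 2: {2.0, 2.0, 2.0} -> sd 0, range 0
        sessions = [
            _fake_session({1: 1.0, 2: 2.0}),
            _fake_session({1: 1.2, 2: 2.0}),
            _fake_session({1: 1.4, 2: 2.0}),
        ]
        res = longitudinal_stats(sessions)
        assert res.sigma_bar == pytest.approx(0.1)
        assert res.mean_range == pytest.approx(0.2)
        assert res.n_markers == 2

    def test_marker_absent_from_one_session_is_excluded(self):
        sessions = [
            _fake_session({1: 1.0, 2: 2.0, 3: 3.0}),
            _fake_session({1: 1.1, 2: 2.1}),
            _fake_session({1: 0.9, 2: 1.9, 3: 3.1}),
        ]
        res = longitudinal_stats(sessions)
        assert res.excluded_ids == (3,)
        assert res.n_markers == 2

    def test_brute_force_oracle_equivalence(self, rng):
        # sigma_bar and mean range against a per-marker loop, 50 random cases
        for _ in range(50):
            n_markers = int(rng.integers(2, 8))
            n_sessions = int(rng.integers(2, 6))
            shifts = rng.uniform(0, 3, (n_markers, n_sessions))
            sessions = [
                _fake_session({m: float(shifts[m, s]) for m in range(n_markers)})
                for s in range(n_sessions)
            ]
            res = longitudinal_stats(sessions)
            sds = [np.std(shifts[m], ddof=1) for m in range(n_markers)]
            ranges = [shifts[m].max() - shifts[m].min() for m in range(n_markers)]
            assert abs(res.sigma_bar - np.mean(sds)) < 1e-12
            assert abs(res.mean_range - np.mean(ranges)) < 1e-12

    def test_requires_two_sessions_and_common_markers(self):
        with pytest.raises(QAError):
            longitudinal_stats([_fake_session({1: 1.0})])
        with pytest.raises(QAError):
            longitudinal_stats([_fake_session({1: 1.0}), _fake_session({2: 1.0})])


class TestToleranceCheck:
    def test_shells_within_25cm_against_2mm_outer_unbounded(self):
        res = _fake_session({1: 0.0})
        res.shell_means = dict(zip(SHELL_LABELS, [0.27, 0.44, 0.82, 2.2, 7.5]))
        res.shell_counts = dict(zip(SHELL_LABELS, [10, 10, 10, 10, 10]))
        report = {r["component"]: r["verdict"] for r in check_tolerance(res)}
        assert report["Distortion d<10cm (3D)"] == "pass"
        assert report["Distortion 10<=d<15cm (3D)"] == "pass"
        assert report["Distortion 15<=d<20cm (3D)"] == "pass"
        assert report["Distortion 20<=d<25cm (3D)"] == "fail"
        assert report["Distortion d>=25cm (3D)"] == "none"

    def test_all_zero_all_pass(self):
        res = _fake_session({1: 0.0})
        res.shell_means = dict(zip(SHELL_LABELS, [0.0] * 5))
        res.shell_counts = dict(zip(SHELL_LABELS, [1] * 5))
        verdicts = [r["verdict"] for r in check_tolerance(res)]
        assert verdicts == ["pass"] * 4 + ["none"]
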