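import math

import numpy as np
import pandas as pd
import pytest

from kirpore import gating
from kirpore.synthetic import GateModel, KineticModel, simulate


def gate_square_tracks(side, n_frames=5, residue="I177"):
    rows = []
    corners = {"A": (side / 2, 0), "B": (0, side / 2),
               "C": (-side / 2, 0), "D": (0, -side / 2)}
    # rotate: square of side a has diagonal a*sqrt2; place atoms at corners
    pts = {"A": (0, 0), "B": (side, 0), "C": (side, side), "D": (0, side)}
    for f in range(n_frames):
        for sub, (x, y) in pts.items():
            rows.append({"frame": f, "time": f * 0.01,
                         "particle": f"{residue}_{sub}", "role": "gate",
                         "x": x, "y": y, "z": -10.0})
    return pd.DataFrame(rows)


class TestGateDiagonalDistance:
    def test_square_gives_side_times_sqrt2(self):
        tracks = gate_square_tracks(4.0)
        _, d = gating.gate_diagonal_distance(tracks, "I177")
        assert np.allclose(d, 4.0 * math.sqrt(2))

    def test_open_state_mean_matches_generator(self):
        gate = GateModel()
        bundle, _ = simulate(KineticModel(), gate, None, duration=5.0,
                             seed=10, dt_ns=2.0)
        _, d = gating.gate_diagonal_distance(bundle.to_track_table(), "I177")
        assert d.mean() == pytest.approx(16.5, abs=0.3)

    def test_closed_state_mean_near_10(self):
        gate = GateModel(closure_rate=1e9)  # closes immediately
        bundle, _ = simulate(KineticModel(), gate, None, duration=2.0,
                             seed=10, dt_ns=2.0)
        _, d = gating.gate_diagonal_distance(bundle.to_track_table(), "I177")
        assert d.mean() == pytest.approx(10.0, abs=0.3)

    def test_wrong_copy_count_rejected(self):
        tracks = gate_square_tracks(4.0)
        tracks = tracks[tracks.particle != "I177_D"]
        with pytest.raises(ValueError, match="4 subunit copies"):
            gating.gate_diagonal_distance(tracks, "I177")


class TestCavityHydration:
    def test_no_waters_gives_zeros(self, geometry):
        tracks = pd.DataFrame({
            "frame": [0, 1], "time": [0.0, 0.01],
            "particle": "ion0", "role": "ion", "x": 0.0, "y": 0.0,
            "z": [-12.0, -12.0],
        })
        _, counts = gating.cavity_hydration(tracks, geometry)
        assert (counts == 0).all()

    def test_open_state_mean_56(self, geometry):
        gate = GateModel()
        bundle, _ = simulate(KineticModel(), gate, None, duration=2.0,
                             seed=3, dt_ns=2.0, include_hydration=True)
        _, counts = gating.cavity_hydration(bundle.to_track_table(), geometry)
        assert counts.mean() == pytest.approx(56.0, abs=2.0)

    def test_matches_brute_force_cylinder_scan(self, geometry):
        rng = np.random.default_rng(0)
        n = 400
        tracks = pd.DataFrame({
            "frame": rng.integers(0, 5, n),
            "time": 0.0,
            "particle": [f"w{i}" for i in range(n)],
            "role": "water",
            "x": rng.uniform(-12, 12, n),
            "y": rng.uniform(-12, 12, n),
            "z": rng.uniform(-30, 10, n),
        })
        tracks["time"] = tracks.frame * 0.01
        _, counts = gating.cavity_hydration(tracks, geometry)
        z_lo, z_hi, r = geometry.cavity_cylinder
        for f in range(5):
            sub = tracks[tracks.frame == f]
            expected = sum(
                1 for _, row in sub.iterrows()
                if row.x ** 2 + row.y ** 2 <= r ** 2 and z_lo <= row.z < z_hi
            )
            assert counts[f] == expected

    def test_permutation_invariant(self, geometry):
        gate = GateModel()
        bundle, _ = simulate(KineticModel(), gate, None, duration=0.2,
                             seed=3, dt_ns=2.0, include_hydration=True)
        tracks = bundle.to_track_table()
        shuffled = tracks.sample(frac=1.0, random_state=1)
        _, a = gating.cavity_hydration(tracks, geometry)
        _, b = gating.cavity_hydration(shuffled, geometry)
        assert np.array_equal(a, b)


class TestDetectClosure:
    def test_drop_and_stay_detected_at_drop(self):
        t = np.arange(100) * 0.5
        counts = np.where(t < 12.0, 56, 30)
        out = gating.detect_closure(t, counts, 35, persistence=4)
        assert out.closed
        assert out.closure_time == pytest.approx(12.0)

    def test_always_hydrated_is_censored(self):
        t = np.arange(50) * 0.5
        out = gating.detect_closure(t, np.full(50, 50), 35, persistence=4)
        assert not out.closed
        assert out.censored_at == pytest.approx(t[-1])

    def test_single_frame_dip_suppressed_by_persistence(self):
        t = np.arange(100) * 0.5
        counts = np.full(100, 50)
        counts[40] = 34
        out = gating.detect_closure(t, counts, 35, persistence=40)
        assert not out.closed

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        t = np.arange(400) * 0.5
        counts = np.where(t < 100, rng.normal(56, 8, 400),
                          rng.normal(20, 5, 400)).round()
        prev = -np.inf
        for thr in (25, 35, 45):
            out = gating.detect_closure(t, counts, thr, persistence=5)
            assert out.closed
            assert out.closure_time <= prev or prev == -np.inf
            prev = out.closure_time

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            gating.detect_closure([], [], 35, 1)


class TestClosureStatistics:
    def test_median_without_censoring(self):
        outs = [gating.ClosureOutcome(x, None) for x in (2.0, 4.0, 6.0)]
        stats = gating.closure_statistics(outs)
        assert stats["median"] == pytest.approx(4.0)
        assert not stats["median_is_lower_bound"]

    def test_median_with_censored_replicate(self):
        outs = [gating.ClosureOutcome(3.0, None),
                gating.ClosureOutcome(5.0, None),
                gating.ClosureOutcome(None, 10.0)]
        stats = gating.closure_statistics(outs)
        assert stats["median"] == pytest.approx(5.0)

    def test_all_censored_reports_lower_bound(self):
        outs = [gating.ClosureOutcome(None, 120.0) for _ in range(5)]
        stats = gating.closure_statistics(outs)
        assert stats["median_is_lower_bound"]
        assert stats["median"] == pytest.approx(120.0)

    def test_survival_median_converges_to_ln2_over_lambda(self):
        rng = np.random.default_rng(4)
        lam = 1.0 / 30.0
        samples = rng.exponential(1 / lam, 500)
        outs = [gating.ClosureOutcome(float(s), None) for s in samples]
        stats = gating.closure_statistics(outs)
        assert stats["median"] == pytest.approx(math.log(2) / lam, rel=0.10)

    def test_fraction_closed_curve_monotone(self):
        outs = [gating.ClosureOutcome(x, None) for x in (1.0, 2.0, 5.0)] + \
            [gating.ClosureOutcome(None, 8.0)]
        curve = gating.closure_statistics(outs)["fraction_closed_curve"]
        assert (np.diff(curve.fraction_closed) >= -1e-12).all()


class TestSeparationsAndContacts:
    def test_coincident_points_zero(self):
        tracks = pd.DataFrame({
            "frame": [0, 0], "time": [0.0, 0.0],
            "particle": ["COM_CTD", "COM_SF"], "role": "landmark",
            "x": [1.0, 1.0], "y": [2.0, 2.0], "z": [3.0, 3.0],
        })
        _, sep = gating.ctd_sf_separation(tracks)
        assert sep[0] == 0.0

    def test_known_distance(self):
        tracks = pd.DataFrame({
            "frame": [0, 0], "time": [0.0, 0.0],
            "particle": ["COM_CTD", "COM_SF"], "role": "landmark",
            "x": [0.0, 1.5], "y": [0.0, 2.0], "z": [0.0, 0.0],
        })
        _, sep = gating.ctd_sf_separation(tracks)
        assert sep[0] == pytest.approx(2.5)

    def test_ctd_approaches_sf_on_opening(self):
        gate = GateModel()
        open_b, _ = simulate(KineticModel(), gate, None, duration=1.0,
                             seed=2, dt_ns=2.0)
        closed_gate = GateModel(closure_rate=1e9)
        closed_b, _ = simulate(KineticModel(), closed_gate, None,
                               duration=1.0, seed=2, dt_ns=2.0)
        _, sep_open = gating.ctd_sf_separation(open_b.to_track_table())
        _, sep_closed = gating.ctd_sf_separation(closed_b.to_track_table())
        approach = sep_closed.mean() - sep_open.mean()
        assert 2.0 <= approach <= 4.0

    def test_contact_min_matches_brute_force(self):
        rng = np.random.default_rng(7)
        rows = []
        for f in range(3):
            for i in range(10):
                rows.append({"frame": f, "time": f * 0.01,
                             "particle": f"a{i}", "role": "gate",
                             "x": rng.normal(), "y": rng.normal(),
                             "z": rng.normal()})
                rows.append({"frame": f, "time": f * 0.01,
                             "particle": f"b{i}", "role": "gate",
                             "x": rng.normal(3), "y": rng.normal(),
                             "z": rng.normal()})
        tracks = pd.DataFrame(rows)
        sel_a = [f"a{i}" for i in range(10)]
        sel_b = [f"b{i}" for i in range(10)]
        _, dmin = gating.contact_distances(tracks, sel_a, sel_b)
        for f in range(3):
            sub = tracks[tracks.frame == f]
            pa = sub[sub.particle.isin(sel_a)][["x", "y", "z"]].to_numpy()
            pb = sub[sub.particle.isin(sel_b)][["x", "y", "z"]].to_numpy()
            brute = min(np.linalg.norm(u - v) for u in pa for v in pb)
            assert dmin[f] == pytest.approx(brute)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            gating.contact_distances(pd.DataFrame(), [], ["b"])
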