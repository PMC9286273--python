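import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nadder.dimdecomp import (Fragment, absorb_short_runs, decompose_at_scale,
                              fragments_from_mask, indicators_at_s,
                              stable_fragments)
from nadder.geometry import differential_profile
from nadder.scales import build_scale_space
from nadder.simulate import simulate_composite

from conftest import rigid_motion


def naive_runs(mask):
    """Brute-force run-length scanner (independent oracle)."""
    runs, start = [], None
    for i, v in enumerate(list(mask) + [0]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    return runs


class TestIndicators:
    def test_straight_line(self, straight_line):
        m = indicators_at_s(differential_profile(straight_line))
        assert m.L.all() and m.T.all()

    def test_planar_circle(self, circle_r2):
        m = indicators_at_s(differential_profile(circle_r2))
        interior = slice(5, -5)
        assert not m.L[interior].any()
        assert m.H[interior].all() and m.T[interior].all()

    def test_helix_fully_3d(self, helix_unit):
        # kappa = tau = 0.5 >> both tolerances
        m = indicators_at_s(differential_profile(helix_unit), 0.01, 0.01)
        interior = slice(20, -20)
        assert not m.L[interior].any()
        assert not m.T[interior].any()

    def test_t_contains_l(self, planar_spiral):
        m = indicators_at_s(differential_profile(planar_spiral))
        assert np.all(m.T >= m.L)


class TestFragmentsFromMask:
    def test_single_run(self):
        frags = fragments_from_mask(np.array([0, 0, 0, 1, 1, 1, 0, 0, 0]),
                                    eps_omega=2.0, spacing=1.0)
        assert [(f.start, f.end) for f in frags] == [(3, 5)]

    def test_below_threshold_dropped(self):
        assert fragments_from_mask(np.array([0, 1, 0]), eps_omega=2.0,
                                   spacing=1.0) == []

    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_eps_omega_zero_equals_run_length_encoding(self, bits):
        """With no length threshold the op is plain run-length encoding."""
        mask = np.array(bits, dtype=bool)
        frags = fragments_from_mask(mask, eps_omega=0.0, spacing=1.0)
        assert [(f.start, f.end) for f in frags] == naive_runs(mask)

    @given(st.lists(st.booleans(), min_size=1, max_size=200),
           st.integers(min_value=1, max_value=8))
    @settings(max_examples=100, deadline=None)
    def test_no_gap_fill_matches_filtered_oracle(self, bits, min_len):
        mask = np.array(bits, dtype=bool)
        frags = fragments_from_mask(mask, eps_omega=float(min_len),
                                    spacing=1.0, fill_gaps=False)
        expected = [(a, b) for a, b in naive_runs(mask)
                    if b - a >= min_len]
        assert [(f.start, f.end) for f in frags] == expected


class TestAbsorbShortRuns:
    def test_absorbs_shortest_first(self):
        labels = np.array([1] * 10 + [2] * 2 + [1] * 10)
        out = absorb_short_runs(labels, eps_omega=5.0, spacing=1.0)
        assert np.all(out == 1)

    def test_no_change_when_all_long(self):
        labels = np.array([1] * 10 + [3] * 10)
        out = absorb_short_runs(labels, eps_omega=5.0, spacing=1.0)
        np.testing.assert_array_equal(out, labels)


class TestStableFragments:
    def test_whole_plane_single_fragment(self, planar_spiral):
        fam = build_scale_space(planar_spiral, [0.0, 1.0, 2.0, 4.0])
        frags, _ = stable_fragments(fam, fam.s_grid, "T", eps_omega=5.0)
        assert len(frags) == 1
        assert frags[0].start == 0
        assert frags[0].end == planar_spiral.n_points - 1

    def test_longest_count_subinterval_wins(self, monkeypatch):
        """Constructed counts [3,3,3,2,2] -> the 3-long subinterval wins."""
        import nadder.dimdecomp as dd

        fam = build_scale_space(
            # any curve; masks are stubbed out below
            dd.Curve3D(np.column_stack([np.arange(50.0), np.zeros(50),
                                        np.zeros(50)])),
            [0.0, 1.0, 2.0, 3.0, 4.0])
        per_s = {
            0.0: [(0, 9), (20, 29), (40, 49)],
            1.0: [(0, 9), (20, 29), (40, 49)],
            2.0: [(0, 11), (20, 29), (40, 49)],
            3.0: [(0, 29), (40, 49)],
            4.0: [(0, 29), (40, 49)],
        }

        def fake_fragments(mask, eps_omega, spacing=1.0, label=2,
                           fill_gaps=True):
            s = fake_fragments.current
            return [Fragment(a, b, label, float(b - a))
                    for a, b in per_s[s]]

        real_indicators = dd.indicators_at_s

        def spy_indicators(profile, eps_kappa=0.01, eps_tau=0.015, s=np.nan):
            fake_fragments.current = s
            return real_indicators(profile, eps_kappa, eps_tau, s=s)

        monkeypatch.setattr(dd, "fragments_from_mask", fake_fragments)
        monkeypatch.setattr(dd, "indicators_at_s", spy_indicators)
        frags, S_sub = dd.stable_fragments(fam, fam.s_grid, "T",
                                           eps_omega=0.0)
        assert list(S_sub) == [0.0, 1.0, 2.0]
        assert len(frags) == 3

    def test_empty_scale_set_errors(self, planar_spiral):
        fam = build_scale_space(planar_spiral, [0.0, 1.0])
        with pytest.raises(ValueError):
            stable_fragments(fam, np.array([]), "T")

    def test_overlap_split_in_half(self, monkeypatch):
        """Overlapping selected fragments are trimmed at the midpoint."""
        import nadder.dimdecomp as dd

        fam = build_scale_space(
            dd.Curve3D(np.column_stack([np.arange(60.0), np.zeros(60),
                                        np.zeros(60)])), [0.0, 1.0])
        per_s = {0.0: [(0, 30), (21, 40)], 1.0: [(0, 24), (26, 59)]}

        def fake_fragments(mask, eps_omega, spacing=1.0, label=2,
                           fill_gaps=True):
            return [Fragment(a, b, label, float(b - a))
                    for a, b in per_s[fake_fragments.current]]

        real_indicators = dd.indicators_at_s

        def spy_indicators(profile, eps_kappa=0.01, eps_tau=0.015, s=np.nan):
            fake_fragments.current = s
            return real_indicators(profile, eps_kappa, eps_tau, s=s)

        monkeypatch.setattr(dd, "fragments_from_mask", fake_fragments)
        monkeypatch.setattr(dd, "indicators_at_s", spy_indicators)
        frags, _ = dd.stable_fragments(fam, fam.s_grid, "T", eps_omega=0.0,
                                       candidate="longest")
        assert len(frags) == 2
        first, second = frags
        assert first.end < second.start  # no overlap left
        # longest candidates were (0,30) and (26,59); overlap 26..30 split
        assert first.end == (30 + 26) // 2
        assert second.start == first.end + 1


class TestDecomposeAtScale:
    def test_straight_line_single_1d_fragment(self, straight_line):
        for r_hat in (5.0, 20.0, 80.0):
            dec = decompose_at_scale(straight_line, r_hat)
            assert len(dec.fragments) == 1
            assert dec.fragments[0].label == 1

    def test_planar_spiral_single_2d_fragment(self, planar_spiral):
        dec = decompose_at_scale(planar_spiral, 10.0)
        labels = set(f.label for f in dec.fragments)
        assert 3 not in labels
        # dominant label is planar
        counts = np.bincount(dec.labels, minlength=4)
        assert counts[2] > 0.8 * planar_spiral.n_points

    def test_tiling_invariant(self):
        rng = np.random.default_rng(0)
        sim = simulate_composite(sigma=2.0, rng=rng)
        dec = decompose_at_scale(sim.curve, 20.0)
        covered = np.zeros(sim.curve.n_points, dtype=int)
        for f in dec.fragments:
            covered[f.start:f.end + 1] += 1
        assert np.all(covered == 1)

    def test_hierarchy_1d_inside_pass1_regions(self):
        rng = np.random.default_rng(1)
        sim = simulate_composite(dims=[2, 1, 3], sigma=0.0, rng=rng)
        dec = decompose_at_scale(sim.curve, 20.0)
        planar_cover = np.zeros(sim.curve.n_points, dtype=bool)
        for f in dec.planar_regions:
            planar_cover[f.start:f.end + 1] = True
        one_d = dec.labels == 1
        # 1D points that came from pass 2 must lie in a pass-1 region
        # (the final absorb step may shift boundaries by < eps_omega)
        assert np.mean(planar_cover[one_d]) > 0.9

    def test_rigid_motion_invariance_of_labels(self):
        rng = np.random.default_rng(3)
        sim = simulate_composite(dims=[1, 3, 2], sigma=0.0, rng=rng)
        R, tr = rigid_motion(np.random.default_rng(4))
        a = decompose_at_scale(sim.curve, 20.0)
        b = decompose_at_scale(sim.curve.transformed(R, tr), 20.0)
        assert np.mean(a.labels == b.labels) > 0.99

    def test_short_curve_warns_single_3d(self, caplog):
        import logging
        from nadder.geometry import Curve3D
        tiny = Curve3D(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0],
                                 [3, 0, 0.]]))
        with caplog.at_level(logging.WARNING, logger="nadder.dimdecomp"):
            dec = decompose_at_scale(tiny, 20.0)
        assert [f.label for f in dec.fragments] == [3]

    def test_noiseless_composite_recovery(self):
        """Clean 5-fragment composite: boundaries within 10 um, F1 = 1.0."""
        from nadder.evaluate import decomposition_accuracy
        rng = np.random.default_rng(42)
        sim = simulate_composite(dims=[1, 2, 3, 2, 1], sigma=0.0, rng=rng)
        fam = build_scale_space(sim.curve)
        best = max(
            decomposition_accuracy(sim.truth_fragments(),
                                   decompose_at_scale(sim.curve, r,
                                                      family=fam).fragments)
            for r in (5.0, 10.0, 20.0))
        assert best >= 0.9
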