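"""Start-point search, candidate geometry, scoring, and the trace loop."""

import numpy as np
import pytest

import mammotrace as mt
from mammotrace import smoothness as sm
from mammotrace.tracer import TraceConfig, _disk_offsets


def brute_force_disk(radius):
    points = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if 0 < dr * dr + dc * dc <= radius * radius:
                points.append((dr, dc))
    return points


class TestCandidatePoints:
    def test_full_disk_count_matches_enumeration(self):
        config = TraceConfig(radius=20)
        cands = mt.candidate_points((500, 500), [], (1000, 1000), config)
        assert len(cands) == len(brute_force_disk(20)) == 1256

    def test_corner_case_hand_enumeration(self):
        config = TraceConfig(radius=2)
        cands = mt.candidate_points((0, 0), [], (100, 100), config)
        expected = {(0, 1), (0, 2), (1, 0), (1, 1), (2, 0)}
        assert {tuple(p) for p in cands} == expected

    def test_row_major_order(self):
        config = TraceConfig(radius=3)
        cands = mt.candidate_points((10, 10), [], (30, 30), config)
        keys = [(r, c) for r, c in cands]
        assert keys == sorted(keys)

    def test_revisit_exclusion_removes_zone(self):
        config = TraceConfig(radius=5, revisit_exclusion=2)
        current, previous = (20, 20), [(19, 19), (20, 20)]
        cands = {tuple(p) for p in
                 mt.candidate_points(current, previous, (50, 50), config)}
        no_hist = {tuple(p) for p in
                   mt.candidate_points(current, [], (50, 50), config)}
        removed = no_hist - cands
        assert removed
        for r, c in removed:
            assert max(abs(r - 19), abs(c - 19)) <= 2
        # points near the current point but outside the zone survive
        assert (22, 22) in cands

    @pytest.mark.parametrize("radius", [2, 5, 11])
    def test_counts_match_oracle_for_radii(self, radius):
        config = TraceConfig(radius=radius)
        cands = mt.candidate_points((100, 100), [], (300, 300), config)
        assert len(cands) == len(brute_force_disk(radius))


class TestScoreCandidate:
    @pytest.fixture()
    def smodel(self):
        return sm.SmoothnessModel(mean=np.zeros(2),
                                  covariance=0.25 * np.eye(2), epsilon=0)

    def test_joint_is_product_and_zero_factor_kills(self):
        score = mt.CandidateScore((1, 1), texture_p=0.8, smooth_p=0.5, prior_p=2.0)
        assert score.joint == pytest.approx(0.8)
        assert mt.CandidateScore((1, 1), 0.0, 0.5, 2.0).joint == 0.0

    def test_mode_t_joint_equals_texture(self, small_archive, smodel):
        config = TraceConfig(mode="T", window=small_archive.window)
        desc = np.zeros(1024)
        desc[::256] = 625.0
        score = mt.score_candidate((10, 10), (5, 5), (0, 0), desc,
                                   small_archive.texture, smodel, config)
        assert score.joint == pytest.approx(score.texture_p)
        assert score.smooth_p == 1.0 and score.prior_p == 1.0

    def test_ts_tiebreak_prefers_slope_nearer_mean(self, small_archive, smodel):
        # two candidates, same descriptor (equal texture probability): the
        # one whose step continues straight down (slope vector at the
        # Gaussian mean) must win over a sharp turn
        config = TraceConfig(mode="TS", window=small_archive.window)
        desc = np.zeros(1024)
        desc[::256] = 625.0
        p_k1, p_k = (0, 10), (5, 10)
        straight = mt.score_candidate((10, 10), p_k, p_k1, desc,
                                      small_archive.texture, smodel, config)
        turn = mt.score_candidate((5, 15), p_k, p_k1, desc,
                                  small_archive.texture, smodel, config)
        assert straight.texture_p == pytest.approx(turn.texture_p)
        assert straight.joint > turn.joint

    def test_missing_history_uses_available_factors(self, small_archive, smodel):
        config = TraceConfig(mode="TSP", window=small_archive.window)
        desc = np.zeros(1024)
        desc[::256] = 625.0
        score = mt.score_candidate((10, 10), (5, 5), None, desc,
                                   small_archive.texture, smodel, config)
        assert score.smooth_p == 1.0
        assert score.joint == pytest.approx(score.texture_p * score.prior_p)

    def test_constant_multiplier_preserves_argmax(self, small_archive, smodel):
        config = TraceConfig(mode="TSP", window=small_archive.window)
        rng = np.random.default_rng(0)
        descs = rng.integers(0, 50, (10, 1024)).astype(float)
        scores = [mt.score_candidate((10 + i, 10), (5, 5), (0, 5), d,
                                     small_archive.texture, smodel, config)
                  for i, d in enumerate(descs)]
        joints = np.array([s.joint for s in scores])
        assert np.argmax(joints) == np.argmax(joints * 17.3)


class TestFindStartPoint:
    def test_start_in_topmost_boundary_row(self, small_dataset, small_archive):
        sample = small_dataset["test"][0]
        start = mt.find_start_point(sample.image, small_archive.texture,
                                    small_archive.window)
        assert start is not None
        # the gt curve reaches the top edge, so the start row is near it
        assert start[0] <= 10
        assert abs(start[1] - sample.gt_boundary[start[0], 1]) <= 15

    def test_background_only_image_returns_none(self, small_archive):
        rng = np.random.default_rng(0)
        background = np.clip(rng.normal(5, 2, (48, 48)), 0, 255).astype(np.uint8)
        assert mt.find_start_point(background, small_archive.texture,
                                   small_archive.window) is None


class TestTraceBoundary:
    def test_trace_recovers_boundary_on_phantom(self, small_dataset, small_archive):
        sample = small_dataset["test"][0]
        boundary = mt.trace_with_archive(sample.image, small_archive, mode="TSP")
        assert len(boundary) >= 5
        gt = sample.gt_boundary
        span = (boundary[:, 0].max() - boundary[:, 0].min()) / (len(gt) - 1)
        assert span >= 0.5
        assert mt.acc_mean(boundary, gt) < 12.0

    def test_black_image_gives_empty_boundary(self, small_archive):
        boundary = mt.trace_boundary(np.zeros((48, 48), np.uint8),
                                     small_archive.texture,
                                     small_archive.smoothness,
                                     TraceConfig(window=small_archive.window))
        assert boundary.shape == (0, 2)

    def test_deterministic(self, small_dataset, small_archive):
        sample = small_dataset["test"][1]
        a = mt.trace_with_archive(sample.image, small_archive, mode="TSP")
        b = mt.trace_with_archive(sample.image, small_archive, mode="TSP")
        assert np.array_equal(a, b)

    def test_consecutive_points_within_radius_and_distinct(
            self, small_dataset, small_archive):
        sample = small_dataset["test"][0]
        boundary = mt.trace_with_archive(sample.image, small_archive, mode="TSP")
        steps = np.diff(boundary, axis=0)
        distances = np.hypot(steps[:, 0], steps[:, 1])
        assert np.all(distances > 0)
        assert np.all(distances <= 20)

    def test_no_accepted_point_repeats(self, small_dataset, small_archive):
        sample = small_dataset["test"][0]
        boundary = mt.trace_with_archive(sample.image, small_archive, mode="TSP")
        assert len({tuple(p) for p in boundary}) == len(boundary)

    def test_accepted_point_maximizes_joint(self, small_dataset, small_archive):
        # re-score the candidate set of a mid-trace step independently
        from mammotrace import lbp
        sample = small_dataset["test"][0]
        config = TraceConfig(mode="TSP", window=small_archive.window)
        boundary = mt.trace_boundary(sample.image, small_archive.texture,
                                     small_archive.smoothness, config)
        k = len(boundary) // 2
        assert k >= 2
        current, prev = tuple(boundary[k - 1]), tuple(boundary[k - 2])
        history = [tuple(p) for p in boundary[:k]]
        cands = mt.candidate_points(current, history, sample.image.shape, config)
        codes = lbp.lbp_image(sample.image)
        best, best_joint = None, -1.0
        for cand in map(tuple, cands):
            desc = lbp.patch_descriptor(codes, cand, config.window)
            if mt.classify(small_archive.texture, desc) != "boundary":
                continue
            score = mt.score_candidate(cand, current, prev, desc,
                                       small_archive.texture,
                                       small_archive.smoothness, config)
            if score.joint > best_joint:
                best, best_joint = cand, score.joint
        assert best == tuple(boundary[k])

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            TraceConfig(mode="SPT")


def test_archive_window_mismatch_refused(small_dataset, small_archive):
    with pytest.raises(ValueError, match="window"):
        mt.trace_with_archive(small_dataset["test"][0].image, small_archive,
                              window=small_archive.window - 10)


def test_disk_offsets_cached_and_correct():
    offsets = _disk_offsets(4)
    assert len(offsets) == len(brute_force_disk(4))
    assert _disk_offsets(4) is _disk_offsets(4)
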