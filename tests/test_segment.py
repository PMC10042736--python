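"""Segmentation unit tests and fragment-merging properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from nucexpel.roc import match_traces_to_truth
from nucexpel.segment import (
    LabeledFrame,
    SegmentationParams,
    merge_fragments,
    segment_frame,
    segment_movie,
)
from nucexpel.track import track_cells


def gaussian_blob(shape, cy, cx, sigma, peak):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return peak * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))


def make_frame(ids, centroids, areas, index=0):
    """Synthetic LabeledFrame for merge/track tests (no pixel data needed)."""
    n = len(ids)
    return LabeledFrame(
        index=index,
        labels=np.zeros((1, 1), dtype=np.int32),
        ids=np.asarray(ids, dtype=np.int32),
        centroids=np.asarray(centroids, dtype=float).reshape(n, 2),
        areas=np.asarray(areas, dtype=float),
        mean_intensity=np.ones(n),
    )


class TestSegmentFrame:
    def test_blank_frame_zero_labels(self):
        lf = segment_frame(np.full((64, 64), 7.0))
        assert lf.n_labels == 0

    def test_nonfinite_pixels_rejected(self):
        img = np.ones((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            segment_frame(img)

    def test_two_separated_blobs_found_with_accurate_centroids(self):
        img = np.full((96, 96), 10.0)
        img += gaussian_blob(img.shape, 30.0, 25.0, 4.0, 200.0)
        img += gaussian_blob(img.shape, 65.0, 70.0, 4.0, 200.0)
        lf = segment_frame(img)
        assert lf.n_labels == 2
        got = lf.centroids[np.argsort(lf.centroids[:, 0])]
        np.testing.assert_allclose(got, [[30, 25], [65, 70]], atol=1.0)

    def test_rendered_disk_area_recovered(self):
        """A flat disk of radius 10 px segments to ~pi*10^2 pixels."""
        yy, xx = np.mgrid[:80, :80]
        img = 5.0 + 100.0 * ((yy - 40) ** 2 + (xx - 40) ** 2 <= 10**2)
        lf = segment_frame(img)
        assert lf.n_labels == 1
        assert lf.areas[0] == pytest.approx(np.pi * 100, rel=0.10)

    def test_min_area_filter(self):
        img = np.full((64, 64), 5.0)
        img[10:12, 10:12] = 500.0  # 4 px speck
        img += gaussian_blob(img.shape, 45.0, 45.0, 4.0, 300.0)
        lf = segment_frame(img, SegmentationParams(min_area=20))
        assert lf.n_labels == 1
        assert np.linalg.norm(lf.centroids[0] - [45, 45]) < 1.0

    def test_global_methods_available(self):
        img = np.full((64, 64), 5.0)
        img += gaussian_blob(img.shape, 32.0, 32.0, 5.0, 200.0)
        for method in ("otsu", "li", 50.0):
            lf = segment_frame(img, SegmentationParams(threshold_method=method))
            assert lf.n_labels == 1

    def test_split_touching_separates_close_nuclei(self):
        img = np.full((80, 80), 5.0)
        img += gaussian_blob(img.shape, 40.0, 30.0, 4.0, 200.0)
        img += gaussian_blob(img.shape, 40.0, 46.0, 4.0, 200.0)
        merged = segment_frame(img, SegmentationParams(threshold_method=10.0))
        split = segment_frame(
            img, SegmentationParams(threshold_method=10.0, split_touching=True)
        )
        assert merged.n_labels == 1
        assert split.n_labels == 2


class TestMergeFragments:
    def test_nearby_labels_merge_additively(self):
        lf = make_frame([1, 2], [[10, 10], [10, 13]], [40.0, 25.0])
        out = merge_fragments(lf, merge_radius=10.0)
        assert out.n_labels == 1
        assert out.areas[0] == 65.0
        np.testing.assert_allclose(
            out.centroids[0], (40 * np.array([10, 10]) + 25 * np.array([10, 13])) / 65
        )

    def test_distant_labels_unchanged(self):
        lf = make_frame([1, 2], [[10, 10], [10, 60]], [40.0, 25.0])
        out = merge_fragments(lf, merge_radius=10.0)
        assert out.n_labels == 2
        np.testing.assert_array_equal(out.areas, lf.areas)

    def test_chain_closure_matches_single_linkage_oracle(self):
        # A-B and B-C within radius, A-C not: single linkage joins all three
        from scipy.cluster.hierarchy import fcluster, linkage

        cents = np.array([[0.0, 0.0], [0.0, 8.0], [0.0, 16.0]])
        lf = make_frame([1, 2, 3], cents, [10.0, 10.0, 10.0])
        out = merge_fragments(lf, merge_radius=10.0)
        oracle = fcluster(linkage(cents, method="single"), t=10.0, criterion="distance")
        assert out.n_labels == len(np.unique(oracle)) == 1
        assert out.areas[0] == 30.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        pts=st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
            ),
            min_size=1,
            max_size=12,
        ),
        radius=st.floats(1, 40),
    )
    def test_merge_is_idempotent(self, pts, radius):
        lf = make_frame(
            np.arange(1, len(pts) + 1), pts, np.ones(len(pts)) * 30.0
        )
        once = merge_fragments(lf, radius)
        twice = merge_fragments(once, radius)
        assert once.n_labels == twice.n_labels
        np.testing.assert_allclose(once.centroids, twice.centroids)
        np.testing.assert_allclose(once.areas, twice.areas)


class TestFidelityOnSimulatedMovies:
    def test_noiseless_well_separated_recovery(self, noiseless_baseline):
        """Trace count = n_cells; areas within 10%; centroid RMSE < 1 px."""
        cfg, movie, truth = noiseless_baseline
        frames = segment_movie(movie.channel("nuclear"))
        traces = track_cells(frames)
        assert len(traces) == cfg.n_cells
        match = match_traces_to_truth(traces, truth)
        sq = []
        for tr in traces:
            g = match[tr.cell_id]
            rel = tr.areas / truth.areas[g, tr.frames] - 1.0
            assert np.abs(rel).max() < 0.10
            sq.append(np.linalg.norm(tr.centroids - truth.centroids[g, tr.frames], axis=1) ** 2)
        rmse = float(np.sqrt(np.concatenate(sq).mean()))
        assert rmse < 1.0

    def test_fragmented_apoptotic_cell_stays_one_object(self):
        from conftest import make_config
        from nucexpel.simulate import simulate_movie

        cfg = make_config(
            n_cells=6, fraction_apoptotic=1.0, fraction_expelling=0.0,
            fragmentation_prob=1.0, noise_enabled=False, drift_sd=0.0, seed=21,
        )
        movie, truth = simulate_movie(cfg)
        frames = segment_movie(movie.channel("nuclear"), merge_radius="auto")
        traces = track_cells(frames)
        long_traces = [t for t in traces if len(t) >= cfg.n_frames - 2]
        assert len(long_traces) == cfg.n_cells
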