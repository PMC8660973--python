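"""Distance profiles, nearest-neighbor statistics, subcluster detection."""

import math

import numpy as np
import pytest

from synmorph.annotations import ValidationError
from synmorph.spatial import (
    SpatialProfile,
    detect_subclusters,
    expected_csr_nn_distance,
    holm_adjust,
    nearest_neighbor_records,
    nn_vs_az_regression,
    normalize_profile,
    sv_distance_profile,
)
from synmorph.simulate import SyntheticParams, generate_csr_field, generate_section

from conftest import make_section


def profile(counts, width=50.0, n_synapses=1, kind="raw", excluded=0):
    counts = np.asarray(counts, dtype=float)
    edges = np.arange(len(counts) + 1) * width
    return SpatialProfile(edges, counts, n_synapses, kind, excluded)


class TestDistanceProfile:
    def test_hand_binnable_case(self):
        s = make_section([(100, 10), (200, 60), (300, 130), (400, 790), (500, 850)])
        prof = sv_distance_profile([s])
        expected = np.zeros(16)
        expected[[0, 1, 2, 15]] = 1
        np.testing.assert_array_equal(prof.counts, expected)
        assert prof.excluded_total == 1

    def test_empty_synapse_gives_zero_profile(self):
        s = make_section([])
        prof = sv_distance_profile([s])
        assert prof.counts.sum() == 0 and prof.excluded_total == 0

    def test_matches_brute_force_histogram(self, rng):
        centers = [(float(x), float(y)) for x, y in
                   np.column_stack([rng.uniform(0, 1000, 150), rng.uniform(0, 1000, 150)])]
        s = make_section(centers)
        prof = sv_distance_profile([s])
        dists = [v.center.y for v in s.vesicles]  # AZ along y=0, x within [0, 1000]
        hist, _ = np.histogram([d for d in dists if d < 800], bins=prof.bin_edges)
        np.testing.assert_array_equal(prof.counts, hist)
        assert prof.excluded_total == sum(d >= 800 for d in dists)

    def test_mean_per_synapse_normalization(self):
        s1 = make_section([(100, 10), (200, 20)], synapse_id="a")
        s2 = make_section([(100, 30)], synapse_id="b")
        prof = sv_distance_profile([s1, s2])
        assert prof.counts[0] == pytest.approx(1.5)
        assert prof.n_synapses == 2

    def test_mass_conservation(self, rng):
        sections = [
            generate_section(SyntheticParams(base_sv_count_mean=50.0), "untreated",
                             seed=i, treatment="untreated", synapse_id=f"s{i}")
            for i in range(5)
        ]
        prof = sv_distance_profile(sections)
        total_svs = sum(
            sum(v.diameter < 100 for v in s.vesicles_of_kind("uncoated")) for s in sections
        )
        assert prof.counts.sum() * prof.n_synapses + prof.excluded_total == pytest.approx(
            total_svs
        )

    def test_bin_width_must_divide_max_distance(self):
        with pytest.raises(ValidationError):
            sv_distance_profile([make_section([])], bin_width=70.0, max_distance=800.0)


class TestNormalizeProfile:
    def test_identity_ratio(self):
        p = profile([3, 2, 1])
        np.testing.assert_allclose(normalize_profile(p, p).counts, 1.0)

    def test_annihilation(self):
        treated, control = profile([0, 0]), profile([10, 10])
        np.testing.assert_allclose(normalize_profile(treated, control).counts, 0.0)

    def test_elementwise_ratio(self):
        ratio = normalize_profile(profile([2, 4]), profile([10, 10])).counts
        np.testing.assert_allclose(ratio, np.asarray([2, 4]) / np.asarray([10, 10]))

    def test_zero_control_bin_is_nan(self):
        ratio = normalize_profile(profile([2, 4]), profile([10, 0])).counts
        assert ratio[0] == pytest.approx(0.2) and np.isnan(ratio[1])

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValidationError):
            normalize_profile(profile([1, 2]), profile([1, 2, 3]))


class TestNearestNeighbor:
    def test_collinear_hand_case(self):
        s = make_section([(0, 500), (60, 500), (200, 500)])
        recs = nearest_neighbor_records(s)
        assert [r.nn_distance for r in recs] == pytest.approx([60.0, 60.0, 140.0])
        assert [r.az_distance for r in recs] == pytest.approx([500.0] * 3)

    def test_single_sv_warns_and_returns_empty(self):
        s = make_section([(100, 100)])
        with pytest.warns(UserWarning, match="fewer than 2 SVs"):
            assert nearest_neighbor_records(s) == []

    def test_excludes_cisterna_like_and_coated(self):
        s = make_section(
            [(0, 500), (60, 500), (62, 500), (65, 500)],
            diameters=[50, 50, 150, 80],
            kinds=["uncoated", "uncoated", "uncoated", "ccv"],
            stages=[None, None, None, 1],
        )
        recs = nearest_neighbor_records(s)
        assert [r.vesicle_id for r in recs] == ["v0", "v1"]
        assert recs[0].nn_distance == pytest.approx(60.0)

    def test_matches_all_pairs_brute_force(self, rng):
        centers = [(float(x), float(y)) for x, y in rng.uniform(0, 2000, size=(200, 2))]
        s = make_section(centers)
        recs = {r.vesicle_id: r.nn_distance for r in nearest_neighbor_records(s)}
        pts = np.asarray(centers)
        for i, v in enumerate(s.vesicles):
            d = np.hypot(pts[:, 0] - pts[i, 0], pts[:, 1] - pts[i, 1])
            d[i] = np.inf
            assert recs[v.id] == pytest.approx(float(d.min()))

    def test_csr_field_matches_poisson_closed_form(self):
        lam = 2.5e-5  # expected mean NN distance 100 nm
        field = generate_csr_field(lam, box=(9000.0, 9000.0), seed=42)
        recs = nearest_neighbor_records(field)
        assert len(recs) >= 1500
        by_id = {v.id: v.center for v in field.vesicles}
        interior = [
            r.nn_distance
            for r in recs
            if 300 <= by_id[r.vesicle_id].x <= 8700 and 300 <= by_id[r.vesicle_id].y <= 8700
        ]
        mean = float(np.mean(interior))
        se = float(np.std(interior, ddof=1) / math.sqrt(len(interior)))
        assert abs(mean - expected_csr_nn_distance(lam)) < 3 * se


class TestRegression:
    def test_exact_line(self):
        recs = make_section([(0, 0)])  # unused; build records directly
        from synmorph.spatial import NNRecord

        records = [
            NNRecord("s", f"v{i}", nn_distance=50.0 + 0.1 * x, az_distance=x)
            for i, x in enumerate((0.0, 100.0, 200.0))
        ]
        reg = nn_vs_az_regression(records)
        assert reg.slope == pytest.approx(0.1)
        assert reg.r_squared == pytest.approx(1.0)

    def test_flat_response(self):
        from synmorph.spatial import NNRecord

        records = [
            NNRecord("s", f"v{i}", nn_distance=60.0, az_distance=x)
            for i, x in enumerate((0.0, 100.0, 200.0, 300.0))
        ]
        reg = nn_vs_az_regression(records)
        assert reg.slope == pytest.approx(0.0)
        assert reg.r_squared == pytest.approx(0.0)

    def test_matches_closed_form_least_squares(self, rng):
        from synmorph.spatial import NNRecord

        x = rng.uniform(0, 800, 100)
        y = 40 + 0.05 * x + rng.normal(0, 10, 100)
        records = [
            NNRecord("s", f"v{i}", nn_distance=float(yi), az_distance=float(xi))
            for i, (xi, yi) in enumerate(zip(x, y))
        ]
        reg = nn_vs_az_regression(records)
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        assert reg.slope == pytest.approx(sxy / sxx)
        assert reg.intercept == pytest.approx(y.mean() - (sxy / sxx) * x.mean())
        assert reg.r_squared == pytest.approx(sxy**2 / (sxx * syy))

    def test_intercept_shift_invariance(self, rng):
        from synmorph.spatial import NNRecord

        x = rng.uniform(0, 800, 50)
        y = 40 + 0.05 * x + rng.normal(0, 5, 50)
        mk = lambda ys: [
            NNRecord("s", f"v{i}", nn_distance=float(v), az_distance=float(xi))
            for i, (xi, v) in enumerate(zip(x, ys))
        ]
        r0, r1 = nn_vs_az_regression(mk(y)), nn_vs_az_regression(mk(y + 123.0))
        assert r1.slope == pytest.approx(r0.slope, abs=1e-9)
        assert r1.r_squared == pytest.approx(r0.r_squared, abs=1e-9)
        assert r1.intercept == pytest.approx(r0.intercept + 123.0, abs=1e-9)

    def test_zero_predictor_variance_is_error(self):
        from synmorph.spatial import NNRecord

        records = [NNRecord("s", f"v{i}", 50.0, 100.0) for i in range(5)]
        with pytest.raises(ValidationError):
            nn_vs_az_regression(records)

    def test_holm_adjustment_monotone_and_bounded(self):
        raw = [0.001, 0.04, 0.3]
        adj = holm_adjust(raw)
        assert np.all(adj >= raw) and np.all(adj <= 1.0)


class TestSubclusters:
    def test_chain_under_threshold_is_one_cluster(self):
        s = make_section([(i * 55.0, 500.0) for i in range(5)])
        lab = detect_subclusters(s)
        assert lab.n_clusters == 1 and lab.cluster_sizes == (5,)

    def test_two_separated_clumps(self):
        clump1 = [(i * 50.0, 500.0) for i in range(10)]
        clump2 = [(i * 50.0, 1050.0) for i in range(10)]
        lab = detect_subclusters(make_section(clump1 + clump2))
        assert lab.n_clusters == 2 and lab.cluster_sizes == (10, 10)

    def test_moving_one_sv_away_increments_cluster_count(self):
        base = [(i * 50.0, 500.0) for i in range(6)]
        lab0 = detect_subclusters(make_section(base))
        moved = base[:-1] + [(base[-1][0] + 500.0, 500.0)]
        lab1 = detect_subclusters(make_section(moved))
        assert lab0.n_clusters == 1 and lab1.n_clusters == 2
        assert 1 in lab1.cluster_sizes

    def test_matches_transitive_closure_oracle(self, rng):
        import networkx as nx

        centers = [(float(x), float(y)) for x, y in rng.uniform(0, 800, size=(120, 2))]
        s = make_section(centers)
        lab = detect_subclusters(s)
        g = nx.Graph()
        g.add_nodes_from(v.id for v in s.vesicles)
        pts = {v.id: (v.center.x, v.center.y) for v in s.vesicles}
        ids = list(pts)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if math.dist(pts[a], pts[b]) <= 60.0:
                    g.add_edge(a, b)
        components = {frozenset(c) for c in nx.connected_components(g)}
        ours = {}
        for vid, c in lab.labels.items():
            ours.setdefault(c, set()).add(vid)
        assert {frozenset(c) for c in ours.values()} == components
        assert lab.n_clusters == len(components)

    def test_labels_deterministic_by_size_then_id(self):
        big = [(i * 50.0, 500.0) for i in range(5)]
        small = [(2000.0, 500.0), (2040.0, 500.0)]
        lab = detect_subclusters(make_section(small + big))
        sizes_by_label = {}
        for vid, c in lab.labels.items():
            sizes_by_label[c] = sizes_by_label.get(c, 0) + 1
        assert sizes_by_label[0] == 5 and sizes_by_label[1] == 2
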