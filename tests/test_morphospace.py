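"""PCA morphospace: eigenstructure, scores, hulls, outlier scoring."""

import numpy as np
import pytest

from fishmorph import (FaunaSpec, align_to_reference, centroid_outlier_score,
                       convex_hull_2d, fit_pca, generate, gpa, group_occupancy,
                       hull_area, mean_shape, nearest_to_mean, shape_at_pc,
                       species_means)
from fishmorph.gpa import AlignmentResult

from conftest import single_group_spec


def fake_alignment(aligned, ids=None, species=None, groups=None):
    n = aligned.shape[0]
    return AlignmentResult(
        aligned=aligned,
        consensus=aligned.mean(axis=0),
        centroid_sizes=np.ones(n),
        specimen_ids=ids or [f"s{i}" for i in range(n)],
        species=species or [f"sp{i}" for i in range(n)],
        groups=groups or ["synthetic"] * n,
        iterations=1, final_change=0.0, tolerance=1e-8, max_iterations=100,
        objective_history=[0.0],
    )


@pytest.fixture
def fauna_model(scheme, template, modes):
    spec = single_group_spec(modes, template, scheme, mode_sd=[0.06, 0.04],
                             n_species=40, noise=0.003, seed=21)
    dataset, truth = generate(spec)
    alignment = align_to_reference(gpa(dataset), template)
    return alignment, fit_pca(alignment), truth


class TestFitPCA:
    def test_rank_one_sample(self, rng):
        """Shapes mean +/- delta have one nonzero eigenvalue, scores +/-|delta|."""
        mean = rng.normal(size=(5, 3))
        delta = rng.normal(size=(5, 3)) * 0.01
        aligned = np.stack([mean + delta, mean - delta, mean + delta, mean - delta])
        model = fit_pca(fake_alignment(aligned))
        assert model.n_components == 1
        np.testing.assert_allclose(np.abs(model.scores[:, 0]),
                                   np.linalg.norm(delta), atol=1e-12)

    def test_matches_direct_covariance_eigendecomposition(self, rng):
        """SVD route agrees with an explicit covariance-matrix oracle."""
        aligned = rng.normal(size=(30, 4, 3)) * 0.05
        model = fit_pca(fake_alignment(aligned))
        flat = aligned.reshape(30, -1)
        cov = np.cov(flat, rowvar=False)
        w, v = np.linalg.eigh(cov)
        w, v = w[::-1], v[:, ::-1]
        K = model.n_components
        np.testing.assert_allclose(model.eigenvalues, w[:K], atol=1e-8)
        for k in range(K):
            dot = abs(model.eigenvectors[k] @ v[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_model_invariants(self, fauna_model):
        _, model, _ = fauna_model
        G = model.eigenvectors @ model.eigenvectors.T
        np.testing.assert_allclose(G, np.eye(model.n_components), atol=1e-9)
        assert np.all(np.diff(model.eigenvalues) <= 1e-15)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(model.variance_fractions.sum(), 1.0, atol=1e-12)

    def test_variance_conservation(self, fauna_model):
        alignment, model, _ = fauna_model
        flat = alignment.flattened()
        total = np.var(flat, axis=0, ddof=1).sum()
        assert model.eigenvalues.sum() == pytest.approx(total, abs=1e-9)

    def test_reconstruction_with_all_components(self, fauna_model):
        alignment, model, _ = fauna_model
        flat = alignment.flattened()
        centered = flat - model.mean_shape.reshape(-1)
        rebuilt = model.scores @ model.eigenvectors
        np.testing.assert_allclose(rebuilt, centered, atol=1e-8)

    def test_scores_invariant_to_specimen_order(self, rng):
        aligned = rng.normal(size=(20, 4, 3)) * 0.05
        a = fit_pca(fake_alignment(aligned))
        perm = rng.permutation(20)
        b = fit_pca(fake_alignment(aligned[perm]))
        np.testing.assert_allclose(b.scores, a.scores[perm], atol=1e-8)

    def test_single_mode_fauna_has_unit_first_fraction(self, scheme, template,
                                                       modes):
        spec = single_group_spec(modes, template, scheme, mode_sd=[0.05],
                                 n_species=12, noise=0.0, nuisance=False, seed=2)
        dataset, _ = generate(spec)
        model = fit_pca(gpa(dataset, tolerance=1e-12))
        assert model.variance_fractions[0] > 0.999

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValueError):
            fit_pca(fake_alignment(rng.normal(size=(2, 4, 3))))


class TestMeanShape:
    def test_identical_shapes(self, rng):
        shape = rng.normal(size=(6, 3))
        from fishmorph import center_scale

        unit = center_scale(shape)
        aligned = np.stack([unit] * 4)
        np.testing.assert_allclose(mean_shape(fake_alignment(aligned)), unit,
                                   atol=1e-12)

    def test_equals_consensus(self, fauna_model):
        alignment, _, _ = fauna_model
        np.testing.assert_allclose(mean_shape(alignment), alignment.consensus,
                                   atol=1e-9)


class TestNearestToMean:
    def test_specimen_at_origin_wins(self, rng):
        mean = rng.normal(size=(4, 3))
        delta = rng.normal(size=(4, 3)) * 0.01
        model = fit_pca(fake_alignment(
            np.stack([mean, mean + delta, mean - delta])))
        # specimen 0 sits exactly at the mean of the +/- pair
        assert nearest_to_mean(model, level="specimen") == "s0"

    def test_score_norm_ordering(self, rng):
        mean = rng.normal(size=(4, 3))
        d1 = rng.normal(size=(4, 3))
        d1 /= np.linalg.norm(d1)
        d2 = rng.normal(size=(4, 3))
        d2 -= (d2.ravel() @ d1.ravel()) * d1
        d2 /= np.linalg.norm(d2)
        # scores (1, 0) and (0, 2) plus balancing specimens
        aligned = np.stack([mean + 1.0 * d1, mean + 2.0 * d2,
                            mean - 1.0 * d1, mean - 2.0 * d2])
        model = fit_pca(fake_alignment(aligned))
        assert nearest_to_mean(model, level="specimen", K_use=2) in ("s0", "s2")

    def test_zero_amplitude_species_identified(self, scheme, template, modes):
        """A species generated at zero mode amplitude is nearest the mean
        when the remaining amplitudes are balanced around zero."""
        from fishmorph import Dataset, LandmarkConfiguration

        amplitudes = {"target": 0.0}
        for j, a in enumerate([0.04, 0.06, 0.08, 0.10]):
            amplitudes[f"plus{j}"] = a
            amplitudes[f"minus{j}"] = -a
        configs = []
        for name, a in amplitudes.items():
            shape = template + a * modes[0].displacement
            for i in range(2):
                configs.append(LandmarkConfiguration(
                    f"{name}_{i}", shape, scheme, species=name))
        model = fit_pca(gpa(Dataset(scheme, configs), tolerance=1e-12))
        assert nearest_to_mean(model, level="species") == "target"


class TestCentroidOutlierScore:
    def test_zero_scores(self):
        assert centroid_outlier_score(np.zeros(4), np.full(4, 0.25)) == 0.0

    def test_arithmetic(self):
        assert centroid_outlier_score(np.array([1.0, -1.0]),
                                      np.array([0.5, 0.25])) == pytest.approx(0.75)

    def test_ranking_matches_recomputation_from_coordinates(self, fauna_model):
        alignment, model, _ = fauna_model
        w = model.variance_fractions
        ours = [centroid_outlier_score(s, w) for s in model.scores]
        # independent route: project centered coordinates directly
        centered = alignment.flattened() - model.mean_shape.reshape(-1)
        redo = [np.sum(w * np.abs(model.eigenvectors @ x)) for x in centered]
        assert np.argsort(ours).tolist() == np.argsort(redo).tolist()
        np.testing.assert_allclose(ours, redo, atol=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            centroid_outlier_score(np.zeros(3), np.zeros(4))


class TestShapeAtPC:
    def test_zero_displacement_is_mean(self, fauna_model):
        _, model, _ = fauna_model
        np.testing.assert_allclose(shape_at_pc(model, 1, t=0.0),
                                   model.mean_shape, atol=1e-12)

    def test_symmetric_displacement(self, fauna_model):
        _, model, _ = fauna_model
        plus = shape_at_pc(model, 2, t=0.05)
        minus = shape_at_pc(model, 2, t=-0.05)
        np.testing.assert_allclose(plus + minus, 2 * model.mean_shape, atol=1e-12)

    def test_projection_round_trip(self, fauna_model):
        """Projecting shape_at_pc back gives score t on PC k, 0 elsewhere."""
        _, model, _ = fauna_model
        t = 0.037
        for k in (1, 2, 3):
            scores = model.project(shape_at_pc(model, k, t=t))
            expected = np.zeros(model.n_components)
            expected[k - 1] = t
            np.testing.assert_allclose(scores, expected, atol=1e-9)

    def test_sd_units(self, fauna_model):
        _, model, _ = fauna_model
        by_sd = shape_at_pc(model, 1, sd_units=2.0)
        by_t = shape_at_pc(model, 1, t=2.0 * np.sqrt(model.eigenvalues[0]))
        np.testing.assert_allclose(by_sd, by_t, atol=1e-12)

    def test_out_of_range(self, fauna_model):
        _, model, _ = fauna_model
        with pytest.raises(ValueError):
            shape_at_pc(model, model.n_components + 1, t=0.1)


def gift_wrap_hull_area(points):
    """O(n^2) Jarvis-march convex hull + shoelace area, independent of Qhull."""
    pts = [tuple(p) for p in np.unique(np.asarray(points, dtype=float), axis=0)]
    if len(pts) < 3:
        return 0.0

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    start = min(pts)
    hull = [start]
    current = start
    while True:
        candidate = pts[0] if pts[0] != current else pts[1]
        for q in pts:
            if q == current:
                continue
            c = cross(current, candidate, q)
            if c < 0 or (c == 0 and
                         np.hypot(q[0] - current[0], q[1] - current[1]) >
                         np.hypot(candidate[0] - current[0],
                                  candidate[1] - current[1])):
                candidate = q
        current = candidate
        if current == start:
            break
        hull.append(current)
    hull = np.array(hull)
    x, y = hull[:, 0], hull[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


class TestConvexHull:
    def test_square_with_interior_point(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        hull = convex_hull_2d(pts)
        assert hull.shape == (4, 2)
        assert hull_area(hull) == pytest.approx(1.0)

    def test_triangle(self):
        pts = np.array([[0, 0], [2, 0], [0, 3]])
        hull = convex_hull_2d(pts)
        assert hull.shape == (3, 2)
        assert hull_area(hull) == pytest.approx(3.0)

    def test_counter_clockwise_order(self):
        hull = convex_hull_2d(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
        x, y = hull[:, 0], hull[:, 1]
        signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert signed > 0

    @pytest.mark.parametrize("pts,expected_rows", [
        (np.array([[2.0, 3.0]]), 1),
        (np.array([[0, 0], [1, 1], [2, 2], [3, 3]]), 2),
    ])
    def test_degenerate_inputs(self, pts, expected_rows):
        hull = convex_hull_2d(pts)
        assert hull.shape[0] == expected_rows
        assert hull_area(hull) == 0.0

    def test_empty_input(self):
        with pytest.raises(ValueError):
            convex_hull_2d(np.empty((0, 2)))

    def test_area_matches_gift_wrapping_oracle(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(rng.integers(4, 25), 2))
            ours = hull_area(convex_hull_2d(pts))
            assert ours == pytest.approx(gift_wrap_hull_area(pts), rel=1e-9)


class TestGroupOccupancy:
    def test_single_group_covers_everything(self, fauna_model):
        _, model, _ = fauna_model
        occ = group_occupancy(model, pc_pair=(1, 2))
        assert set(occ) == {"synthetic"}
        assert occ["synthetic"]["n_species"] == len(set(model.species))

    def test_two_species_group_has_zero_area(self, scheme, template, modes,
                                             small_fauna):
        dataset, _ = small_fauna
        alignment = gpa(dataset)
        model = fit_pca(alignment)
        occ = group_occupancy(model)
        two_sp = [g for g, info in occ.items() if info["n_species"] == 2]
        for g in two_sp:
            assert occ[g]["area"] == 0.0
        assert sum(info["n_species"] for info in occ.values()) == len(
            set(model.species))

    def test_designed_offsets_separate_groups(self, scheme, template, modes):
        """Groups pushed apart along mode 1 occupy disjoint score ranges."""
        spec = FaunaSpec(
            template=template, modes=list(modes[:1]), mode_sd=np.array([0.005]),
            group_offsets={"non-teleost": np.array([0.3]),
                           "ovalentarian acanthomorph": np.array([-0.3])},
            n_species={"non-teleost": 6, "ovalentarian acanthomorph": 6},
            specimens_per_species=1, landmark_noise_sd=0.0, nuisance=True,
            seed=4, scheme=scheme)
        dataset, _ = generate(spec)
        model = fit_pca(gpa(dataset))
        occ = group_occupancy(model, pc_pair=(1, 2))
        a = occ["non-teleost"]["points"][:, 0]
        b = occ["ovalentarian acanthomorph"]["points"][:, 0]
        assert a.min() > b.max() or b.min() > a.max()


class TestSpeciesMeans:
    def test_mean_of_member_scores(self, fauna_model):
        _, model, _ = fauna_model
        for summary in species_means(model):
            member = np.stack([s for s, sp in zip(model.scores, model.species)
                               if sp == summary.species])
            np.testing.assert_allclose(summary.mean_scores, member.mean(axis=0),
                                       atol=1e-12)
            assert summary.n_specimens == member.shape[0]
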