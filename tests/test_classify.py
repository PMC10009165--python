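"""PCA reduction, DBSCAN clustering, bimodality refinement, class
merging and area fractions."""

import numpy as np
import pandas as pd
import pytest

from filamorph import classify as cls


def brute_force_dbscan(Z, eps, min_pts):
    """Independent density-reachability closure.

    Returns (labels_by_component_for_cores, core_flags, noise_flags,
    border_candidates): cores are partitioned by connected components of
    the eps-graph restricted to cores; border points list every adjacent
    core component they could join.
    """
    Z = np.asarray(Z, dtype=float)
    n = len(Z)
    d = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1))
    neigh = d <= eps
    core = neigh.sum(1) >= min_pts
    comp = -np.ones(n, dtype=int)
    cid = 0
    for i in range(n):
        if core[i] and comp[i] < 0:
            stack = [i]
            comp[i] = cid
            while stack:
                j = stack.pop()
                for k in np.nonzero(neigh[j] & core)[0]:
                    if comp[k] < 0:
                        comp[k] = cid
                        stack.append(k)
            cid += 1
    border_options = {}
    noise = np.zeros(n, dtype=bool)
    for i in range(n):
        if core[i]:
            continue
        opts = {comp[j] for j in np.nonzero(neigh[i] & core)[0]}
        if opts:
            border_options[i] = opts
        else:
            noise[i] = True
    return comp, core, noise, border_options


def check_against_oracle(Z, eps, min_pts):
    labels = cls.cluster_dbscan(Z, eps, min_pts)
    comp, core, noise, border = brute_force_dbscan(Z, eps, min_pts)
    # noise sets agree
    np.testing.assert_array_equal(labels == -1, noise)
    # core partition agrees up to label permutation
    mapping = {}
    for i in np.nonzero(core)[0]:
        key = comp[i]
        if key in mapping:
            assert labels[i] == mapping[key]
        else:
            assert labels[i] not in mapping.values()
            mapping[key] = labels[i]
    # border points joined one of their admissible components
    for i, opts in border.items():
        assert labels[i] in {mapping[o] for o in opts}


class TestFitPca:
    def test_collinear_data_needs_one_component(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, 2 * t, -t])
        basis, Z = cls.fit_pca(X, 0.90)
        assert basis.n_kept == 1
        assert Z.shape == (50, 1)

    def test_isotropic_gaussian_needs_two(self):
        rng = np.random.default_rng(0)
        basis, _ = cls.fit_pca(rng.standard_normal((10_000, 2)), 0.90)
        assert basis.n_kept == 2

    def test_full_variance_target_keeps_rank(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((100, 2))
        X = A @ rng.standard_normal((2, 5))      # rank 2 in 5 columns
        basis, _ = cls.fit_pca(X, 1.0)
        assert basis.n_kept == 2

    def test_variance_ratios_non_increasing(self):
        rng = np.random.default_rng(2)
        basis, _ = cls.fit_pca(rng.standard_normal((200, 6)) *
                               [5, 4, 3, 2, 1, 0.5], 0.90)
        assert (np.diff(basis.explained_variance_ratio) <= 1e-12).all()

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            cls.fit_pca(np.eye(3), 0.0)


class TestDbscan:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        eps = 1.0
        a = rng.normal(0, 0.2, (20, 2))
        b = rng.normal(0, 0.2, (20, 2)) + [10 * eps, 0]
        labels = cls.cluster_dbscan(np.vstack([a, b]), eps, 3)
        assert set(labels) == {0, 1}
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_isolated_point_is_noise(self):
        Z = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [50.0, 50.0]])
        labels = cls.cluster_dbscan(Z, 1.0, 3)
        assert labels[3] == -1

    def test_identical_points_form_one_cluster(self):
        labels = cls.cluster_dbscan(np.zeros((7, 3)), 0.5, 3)
        assert (labels == 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_density_reachability_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        dims = int(rng.integers(1, 8))
        Z = rng.normal(0, 1, (n, dims)) * rng.uniform(0.5, 2)
        eps = float(rng.uniform(0.3, 1.5))
        min_pts = int(rng.integers(2, 6))
        check_against_oracle(Z, eps, min_pts)

    def test_estimate_eps_positive_and_deterministic(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((100, 3))
        e1 = cls.estimate_eps(Z, 3)
        e2 = cls.estimate_eps(Z, 3)
        assert e1 == e2 > 0


class TestBimodality:
    def test_gaussian_below_cutoff(self):
        rng = np.random.default_rng(0)
        b = cls.bimodality_coefficient(rng.normal(0, 1, 4000))
        assert abs(b - 1.0 / 3.0) < 0.05
        assert b < cls.BIMODALITY_CUTOFF

    def test_balanced_two_point_mixture_above_cutoff(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-3, 0.5, 200),
                            rng.normal(3, 0.5, 200)])
        assert cls.bimodality_coefficient(x) > cls.BIMODALITY_CUTOFF


class TestRefine:
    def mixture_class(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        comp = np.repeat([0, 1], n // 2)
        x = np.where(comp == 0, rng.normal(-3, 0.5, n), rng.normal(3, 0.5, n))
        Z = np.column_stack([x, rng.normal(0, 1, n)])
        return Z, comp

    def test_bimodal_class_split_recovers_components(self):
        Z, comp = self.mixture_class()
        labels = np.zeros(len(Z), dtype=int)
        refined = cls.refine_classes(labels, Z, np.ones(len(Z)), seed=0)
        assert set(refined) == {0, 1}
        agree = max((refined == comp).mean(), (refined != comp).mean())
        assert agree >= 0.95

    def test_unimodal_class_untouched(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(0, 1, (400, 3))
        labels = np.zeros(400, dtype=int)
        refined = cls.refine_classes(labels, Z, np.ones(400), seed=0)
        assert (refined == 0).all()

    def test_tiny_class_never_split(self):
        Z = np.array([[-3.0], [-3.1], [3.0], [3.1], [2.9]])
        labels = np.zeros(5, dtype=int)
        refined = cls.refine_classes(labels, Z, np.ones(5), seed=0)
        assert (refined == 0).all()

    def test_candidates_ranked_by_mean_area_not_population(self):
        # class 1 is small in number but large in area: with top_k=1 only
        # class 1 may be split
        Z1, _ = self.mixture_class(seed=3, n=400)
        Z2, _ = self.mixture_class(seed=4, n=40)
        Z = np.vstack([Z1, Z2])
        labels = np.concatenate([np.zeros(400, int), np.ones(40, int)])
        areas = np.concatenate([np.full(400, 20.0), np.full(40, 300.0)])
        refined = cls.refine_classes(labels, Z, areas, refine_top_k=1,
                                     seed=0)
        assert set(refined[:400]) == {0}          # populous class intact
        assert len(set(refined[400:])) == 2       # large-area class split


class TestMergeAndFractions:
    def block_profiles(self, seed=0, n_images=12):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.5, 2.0, (n_images, 3))      # 3 latent groups
        cols = []
        owners = []
        for g, w in [(0, 0.6), (0, 0.4), (1, 0.7), (1, 0.3), (2, 0.5),
                     (2, 0.5)]:
            cols.append(f[:, g] * w * (1 + rng.normal(0, 0.02, n_images)))
            owners.append(g)
        M = np.column_stack(cols)
        M = M / M.sum(1, keepdims=True)
        return pd.DataFrame(M, columns=range(6)), owners

    def test_block_structure_recovered(self):
        fr, owners = self.block_profiles()
        mapping = cls.merge_classes(fr, merged_k=3)
        groups = {}
        for c, o in zip(fr.columns, owners):
            groups.setdefault(o, set()).add(mapping[c])
        merged_ids = [g.pop() for g in groups.values() if len(g) == 1]
        assert len(merged_ids) == 3 and len(set(merged_ids)) == 3

    def test_identical_columns_always_merged(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 1.0, 10)
        other = rng.uniform(0.1, 1.0, (10, 4))
        M = np.column_stack([base, base] + list(other.T))
        M = M / M.sum(1, keepdims=True)
        fr = pd.DataFrame(M, columns=range(6))
        mapping = cls.merge_classes(fr, merged_k=3)
        assert mapping[0] == mapping[1]

    def test_output_has_exactly_merged_k_groups(self):
        fr, _ = self.block_profiles(seed=5)
        mapping = cls.merge_classes(fr, merged_k=3)
        assert len(set(mapping.values())) == 3

    def test_fewer_fine_than_merged_is_identity(self, caplog):
        fr = pd.DataFrame(np.random.default_rng(0).uniform(
            0, 1, (5, 2)), columns=[0, 1])
        with caplog.at_level("WARNING", logger="filamorph.classify"):
            mapping = cls.merge_classes(fr, merged_k=3)
        assert mapping == {0: 0, 1: 1}

    def test_too_few_images_rejected(self):
        fr = pd.DataFrame(np.ones((2, 5)))
        with pytest.raises(ValueError):
            cls.merge_classes(fr, merged_k=3)

    def test_area_fraction_arithmetic(self):
        labels = np.array([0, 1, 2])
        areas = np.array([10.0, 30.0, 60.0])
        prof = cls.area_fractions(labels, areas, ["i", "i", "i"])["i"]
        assert prof.fractions == {0: pytest.approx(0.1),
                                  1: pytest.approx(0.3),
                                  2: pytest.approx(0.6)}
        assert prof.noise_fraction == 0.0

    def test_single_class_fraction_one(self):
        prof = cls.area_fractions(np.zeros(4, int), np.ones(4),
                                  ["a"] * 4)["a"]
        assert prof.fractions[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one_with_noise_reported(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(-1, 3, 200)
        areas = rng.uniform(10, 400, 200)
        imgs = rng.choice(["a", "b", "c"], 200)
        for prof in cls.area_fractions(labels, areas, imgs).values():
            assert abs(sum(prof.fractions.values()) - 1.0) <= 1e-12
            assert 0.0 <= prof.noise_fraction <= 1.0

    def test_image_without_classified_objects_flagged(self):
        labels = np.array([-1, -1, 0])
        areas = np.array([5.0, 6.0, 7.0])
        profs = cls.area_fractions(labels, areas, ["x", "x", "y"])
        assert not profs["x"].defined
        assert profs["y"].defined

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, (30, 2))
        b = rng.normal(0, 0.1, (30, 2)) + [5, 5]
        Z = np.vstack([a, b])
        lab = cls.cluster_dbscan(Z, 0.8, 3)
        perm = rng.permutation(len(Z))
        lab_p = cls.cluster_dbscan(Z[perm], 0.8, 3)
        # same partition up to label names
        for i in range(len(Z)):
            for j in range(i):
                assert (lab[perm[i]] == lab[perm[j]]) == \
                    (lab_p[i] == lab_p[j])
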