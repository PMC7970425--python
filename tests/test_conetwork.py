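import numpy as np
import pandas as pd
import pytest

from micronet.conetwork import (
    consensus_tom,
    detect_modules,
    kme,
    module_eigengene,
    pick_soft_threshold,
    scale_free_fit,
    signed_adjacency,
    tom,
)


def tom_oracle(a):
    """Definitional O(n^3) topological overlap."""
    a = np.asarray(a, float).copy()
    np.fill_diagonal(a, 0.0)
    n = len(a)
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def block_tom(sizes, within=0.9, between=0.02, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    t = np.full((n, n), between) + rng.uniform(0, 0.005, (n, n))
    t = (t + t.T) / 2
    start = 0
    for s in sizes:
        t[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(t, 1.0)
    return t


class TestSignedAdjacency:
    def test_exact_correlations(self):
        x1 = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.column_stack([x1, x1, -x1, [1, -1, 1, -1]])
        # columns: self (cor 1), anti (cor -1), orthogonal-ish
        a = signed_adjacency(x, beta=6).to_numpy()
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0)

    def test_zero_correlation_case(self):
        x = np.column_stack([[1, -1, 1, -1], [1, 1, -1, -1]])  # exactly uncorrelated
        a = signed_adjacency(x, beta=6).to_numpy()
        assert a[0, 1] == pytest.approx(0.5**6)

    def test_zero_variance_column_flagged(self):
        x = np.column_stack([[1.0, 2, 3, 4], [5.0, 5, 5, 5]])
        with pytest.warns(UserWarning, match="zero-variance"):
            a = signed_adjacency(x, beta=2).to_numpy()
        assert a[0, 1] == pytest.approx(0.25)  # cor treated as 0
        assert a[1, 1] == 1.0

    def test_validation(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(ValueError):
            signed_adjacency(x, beta=0)
        with pytest.raises(ValueError):
            signed_adjacency(x[:2], beta=2)


class TestTOM:
    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.uniform(0, 1, (10, 10))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            ours = tom(a).to_numpy()
            np.testing.assert_allclose(ours, tom_oracle(a), atol=1e-12)

    def test_complete_unit_graph_is_all_ones(self):
        a = np.ones((5, 5))
        np.testing.assert_allclose(tom(a).to_numpy(), 1.0)

    def test_three_node_hand_case(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        t = tom(a).to_numpy()
        # l = 0.25, (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert t[0, 1] == pytest.approx(0.5)

    def test_empty_graph(self):
        t = tom(np.eye(4)).to_numpy()
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(t[off], 0.0)

    def test_rejects_asymmetric_or_out_of_range(self):
        with pytest.raises(ValueError):
            tom(np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError):
            tom(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestConsensusTOM:
    def test_idempotent_on_identical_inputs(self):
        t = block_tom([5, 5])
        np.testing.assert_allclose(consensus_tom(t, t).to_numpy(), t, atol=1e-12)

    def test_bounded_by_both_inputs_after_scaling(self):
        rng = np.random.default_rng(1)
        t1 = block_tom([6, 6], within=0.8, seed=1)
        t2 = block_tom([6, 6], within=0.5, seed=2)
        cons = consensus_tom(t1, t2).to_numpy()
        off = ~np.eye(len(t1), dtype=bool)
        assert (cons[off] <= t1[off] + 1e-12).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            consensus_tom(np.eye(3), np.eye(4))

    def test_condition_specific_module_collapses(self):
        """A module present in only one condition loses its within-module
        overlap in the consensus."""
        rng = np.random.default_rng(0)
        n_samp, size = 30, 20
        f = rng.normal(size=n_samp)  # PL-only module factor
        g = rng.normal(size=n_samp)  # shared module factor (both conditions)
        pl_only = f[:, None] * 1.2 + rng.normal(0, 0.5, (n_samp, size))
        shared = g[:, None] * 1.2 + rng.normal(0, 0.5, (n_samp, size))
        x_pl = np.hstack([pl_only, shared, rng.normal(size=(n_samp, 30))])
        x_br = np.hstack(
            [rng.normal(size=(n_samp, size)),  # PL-only module absent here
             g[:, None] * 1.2 + rng.normal(0, 0.5, (n_samp, size)),
             rng.normal(size=(n_samp, 30))]
        )
        t_pl = tom(signed_adjacency(x_pl, beta=6)).to_numpy()
        t_br = tom(signed_adjacency(x_br, beta=6)).to_numpy()
        cons = consensus_tom(t_pl, t_br).to_numpy()
        within = t_pl[:size, :size][~np.eye(size, dtype=bool)]
        cons_within = cons[:size, :size][~np.eye(size, dtype=bool)]
        shared_cons = cons[size:2 * size, size:2 * size][~np.eye(size, dtype=bool)]
        off = ~np.eye(len(cons), dtype=bool)
        assert within.mean() > 5 * np.median(t_pl[off])
        assert cons_within.mean() < within.mean() / 3
        assert shared_cons.mean() > cons_within.mean() * 3  # shared module survives


class TestScaleFreeFit:
    def test_exact_power_law_fits_perfectly(self):
        # degree sequence drawn exactly from p(k) ~ k^-2.5
        ks = np.arange(1, 11, dtype=float)
        pk = ks**-2.5
        pk /= pk.sum()
        counts = np.round(pk * 10000).astype(int)
        k = np.repeat(ks, counts)
        r2, slope = scale_free_fit(k, n_bins=10)
        assert r2 >= 0.99
        assert slope < 0

    def test_uniform_degrees_rejected(self):
        rng = np.random.default_rng(0)
        k = rng.uniform(9.9, 10.1, 500)
        r2, slope = scale_free_fit(k)
        assert not (r2 >= 0.8)  # no scale-free structure (NaN or low)

    def test_selection_rule(self):
        rng = np.random.default_rng(0)
        xs = {"PL": rng.normal(size=(20, 40)), "BR": rng.normal(size=(20, 40))}
        beta, fits = pick_soft_threshold(xs, powers=[2, 3, 4], r2_target=-1.0)
        assert beta == 2  # everything passes -> smallest power
        with pytest.warns(UserWarning, match="no power reaches"):
            beta_hi, _ = pick_soft_threshold(xs, powers=[2, 3, 4], r2_target=2.0)
        assert beta_hi in (2, 3, 4)
        assert set(fits["power"]) == {2, 3, 4}
        assert set(fits["condition"]) == {"PL", "BR"}


class TestEigengenes:
    def test_identical_profiles_give_perfect_membership(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=26)
        x = pd.DataFrame(np.column_stack([prof] * 5), columns=[f"o{i}" for i in range(5)])
        labels = pd.Series(1, index=x.columns)
        eg = module_eigengene(x, labels)
        k = kme(x, eg)
        np.testing.assert_allclose(k.to_numpy(), 1.0, atol=1e-9)
        assert eg["MM1"].std(ddof=1) == pytest.approx(1.0)

    def test_sign_oriented_to_mean_profile(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=30)
        x = pd.DataFrame(
            f[:, None] * rng.uniform(0.5, 1.5, 8) + rng.normal(0, 0.4, (30, 8)),
            columns=[f"o{i}" for i in range(8)],
        )
        eg = module_eigengene(x, pd.Series(1, index=x.columns))
        members_z = (x - x.mean()) / x.std(ddof=1)
        assert np.corrcoef(eg["MM1"], members_z.mean(axis=1))[0, 1] > 0

    def test_variance_explained_matches_svd_oracle(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(rng.normal(size=(20, 6)), columns=[f"o{i}" for i in range(6)])
        eg = module_eigengene(x, pd.Series(1, index=x.columns))
        z = ((x - x.mean()) / x.std(ddof=1)).to_numpy()
        s = np.linalg.svd(z, compute_uv=False)
        assert eg.attrs["variance_explained"]["MM1"] == pytest.approx(s[0] ** 2 / (s**2).sum())

    def test_invariant_to_member_ordering(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(rng.normal(size=(15, 10)), columns=[f"o{i}" for i in range(10)])
        labels = pd.Series([1] * 5 + [2] * 5, index=x.columns)
        eg1 = module_eigengene(x, labels)
        perm = rng.permutation(10)
        x2 = x.iloc[:, perm]
        eg2 = module_eigengene(x2, labels.iloc[perm])
        np.testing.assert_allclose(eg1.to_numpy(), eg2.to_numpy(), atol=1e-9)

    def test_single_member_module_warns(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        labels = pd.Series([1, 1, 2], index=x.columns)
        with pytest.warns(UserWarning, match="single member"):
            eg = module_eigengene(x, labels)
        assert eg["MM2"].std(ddof=1) == pytest.approx(1.0)

    def test_noise_otu_has_low_membership(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=26)
        module = f[:, None] + rng.normal(0, 0.3, (26, 20))
        noise = rng.normal(size=(26, 1))
        x = pd.DataFrame(np.hstack([module, noise]),
                         columns=[f"o{i}" for i in range(21)])
        labels = pd.Series([1] * 20 + [0], index=x.columns)
        eg = module_eigengene(x, labels)
        k = kme(x, eg)
        assert abs(k.loc["o20", "MM1"]) < 0.5
        assert (k.to_numpy() >= -1).all() and (k.to_numpy() <= 1).all()


class TestDetectModules:
    def test_perfect_blocks_recovered_exactly(self):
        t = block_tom([30, 25, 22])
        mods = detect_modules(t, min_module_size=20)
        assert mods.n_modules == 3
        assert mods.n_unassigned == 0
        assert sorted(mods.module_sizes.values(), reverse=True) == [30, 25, 22]

    def test_pure_noise_mostly_unassigned(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(26, 200))
        t = tom(signed_adjacency(x, beta=6)).to_numpy()
        mods = detect_modules(t, min_module_size=20)
        assert mods.n_unassigned / 200 > 0.8

    def test_min_module_size_validation(self):
        with pytest.raises(ValueError):
            detect_modules(np.eye(10), min_module_size=2)

    def test_deterministic(self, study_scale_dataset):
        from micronet.data_model import (
            condition_network_inputs,
            filter_rare_otus,
            to_relative_abundance,
        )

        filt, _ = filter_rare_otus(study_scale_dataset.otus)
        rel = to_relative_abundance(filt)
        xs = condition_network_inputs(rel)
        toms = {c: tom(signed_adjacency(x, beta=8)) for c, x in xs.items()}
        cons = consensus_tom(toms["PL"], toms["BR"])
        m1 = detect_modules(cons, x_by_condition=xs)
        m2 = detect_modules(cons, x_by_condition=xs)
        pd.testing.assert_series_equal(m1.labels, m2.labels)

    def test_eigengene_merge_joins_split_module(self):
        """Two blocks driven by the same latent factor merge at the eigengene
        stage."""
        rng = np.random.default_rng(8)
        f = rng.normal(size=30)
        g = rng.normal(size=30)
        blocks = []
        for factor, noise in [(f, 0.3), (f, 0.35), (g, 0.3)]:
            blocks.append(factor[:, None] + rng.normal(0, noise, (30, 22)))
        x = np.hstack(blocks)
        xs = {"PL": x, "BR": x + rng.normal(0, 0.05, x.shape)}
        t = tom(signed_adjacency(x, beta=6))
        mods = detect_modules(t, x_by_condition=xs, min_module_size=20)
        labels = mods.labels.to_numpy()
        # the two f-driven blocks end up in the same module, g separate
        assert labels[0] == labels[30]
        assert labels[0] != labels[50]
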