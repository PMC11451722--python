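from itertools import permutations

import numpy as np
import pytest

import neurodyn as nd
from neurodyn.tensor import (CPFactors, FeatureTensor, SupervisionSpec,
                             assemble_tensor, cp_decompose,
                             denormalize_tensor, explained_fit,
                             normalize_tensor, project_subjects, reconstruct,
                             supervised_cp)


def _exact_rank(shapes, rank, seed):
    rng = np.random.default_rng(seed)
    facs = [rng.standard_normal((d, rank)) for d in shapes]
    T = np.einsum("ir,jr,kr,lr->ijkl", *facs)
    return T, facs


def _congruence(F, true_factors):
    """Best min-mode-column congruence over component permutations."""
    rank = F.rank
    best = -1.0
    for perm in permutations(range(rank)):
        worst = 1.0
        for mode in range(4):
            est = F.factors[mode][:, list(perm)]
            tru = true_factors[mode] / np.linalg.norm(true_factors[mode],
                                                      axis=0)
            c = np.abs(np.sum(est * tru, axis=0))
            worst = min(worst, float(c.min()))
        best = max(best, worst)
    return best


class TestAssemble:
    def test_dims_and_alignment(self, tiny_feature_tables):
        tables, cohort = tiny_feature_tables
        T = assemble_tensor(tables, cohort)
        assert T.shape == (6, 3, 6, 15)
        assert T.labels["subject"] == list(cohort["subject_id"])
        assert T.labels["sensor"] == sorted(T.labels["sensor"])

    def test_single_subject_matches_its_table(self, tiny_feature_tables):
        tables, cohort = tiny_feature_tables
        sid = cohort["subject_id"].iloc[0]
        T = assemble_tensor({sid: tables[sid]}, cohort.iloc[:1])
        row = tables[sid].iloc[0]
        i = T.labels["sensor"].index(row["channel"])
        j = T.labels["band"].index(row["band"])
        k = T.labels["measure"].index("power")
        assert T.values[0, i, j, k] == row["power"]

    def test_missing_channel_masked(self, tiny_feature_tables):
        tables, cohort = tiny_feature_tables
        sid0, sid1 = cohort["subject_id"].iloc[:2]
        partial = {sid0: tables[sid0],
                   sid1: tables[sid1][tables[sid1].channel != "F3"]}
        T = assemble_tensor(partial, cohort.iloc[:2])
        f3 = T.labels["sensor"].index("F3")
        assert T.mask[1, f3].all()
        assert not T.mask[0, f3].any()

    def test_duplicate_subjects_rejected(self, tiny_feature_tables):
        tables, cohort = tiny_feature_tables
        bad = cohort.iloc[[0, 0]].copy()
        with pytest.raises(ValueError):
            assemble_tensor(tables, bad)


class TestNormalize:
    def test_zscore_per_measure(self, tiny_feature_tables):
        tables, cohort = tiny_feature_tables
        T = normalize_tensor(assemble_tensor(tables, cohort))
        for k in range(T.shape[3]):
            obs = T.values[..., k][~T.mask[..., k]]
            assert abs(obs.mean()) < 1e-10
            assert abs(obs.std() - 1.0) < 1e-10

    def test_constant_slice_zeroed_and_flagged(self):
        values = np.random.default_rng(0).standard_normal((4, 2, 2, 2))
        values[..., 1] = 7.0
        T = FeatureTensor(values=values, mask=np.zeros_like(values, bool),
                          labels={"subject": list("abcd"),
                                  "sensor": ["s1", "s2"],
                                  "band": ["b1", "b2"],
                                  "measure": ["m1", "m2"]})
        Tn = normalize_tensor(T)
        assert (Tn.values[..., 1] == 0).all()
        assert Tn.meta["normalization"]["degenerate_measures"] == ["m2"]

    def test_roundtrip(self, tiny_feature_tables):
        tables, cohort = tiny_feature_tables
        T = assemble_tensor(tables, cohort)
        back = denormalize_tensor(normalize_tensor(T))
        np.testing.assert_allclose(back.values[~T.mask], T.values[~T.mask],
                                   atol=1e-10)


class TestCPDecompose:
    def test_exact_rank_one_recovered(self):
        T, _ = _exact_rank((6, 5, 4, 3), 1, seed=0)
        F = cp_decompose(T, rank=1, seed=0)
        rel = np.linalg.norm(T - reconstruct(F)) / np.linalg.norm(T)
        assert rel < 1e-6

    def test_exact_rank_three_congruence(self):
        T, facs = _exact_rank((20, 6, 5, 4), 3, seed=1)
        F = cp_decompose(T, rank=3, seed=0)
        assert _congruence(F, facs) > 0.99

    def test_fit_nested_in_rank(self):
        T, _ = _exact_rank((10, 5, 4, 3), 3, seed=2)
        T += 0.1 * np.random.default_rng(3).standard_normal(T.shape)
        f1 = cp_decompose(T, rank=1, seed=0).fit
        f3 = cp_decompose(T, rank=3, seed=0).fit
        assert f3 >= f1

    def test_seeded_determinism(self):
        T, _ = _exact_rank((8, 4, 4, 3), 2, seed=4)
        T += 0.05 * np.random.default_rng(5).standard_normal(T.shape)
        F1 = cp_decompose(T, rank=2, seed=11)
        F2 = cp_decompose(T, rank=2, seed=11)
        for a, b in zip(F1.factors, F2.factors):
            np.testing.assert_array_equal(a, b)

    def test_weights_descending_unit_columns(self):
        T, _ = _exact_rank((10, 5, 4, 3), 3, seed=6)
        F = cp_decompose(T, rank=3, seed=0)
        assert (np.diff(F.weights) <= 1e-9).all()
        for fac in F.factors:
            np.testing.assert_allclose(np.linalg.norm(fac, axis=0), 1.0,
                                       atol=1e-9)

    def test_masked_cells_never_influence_fit(self):
        T, _ = _exact_rank((8, 4, 4, 3), 2, seed=7)
        mask = np.zeros(T.shape, dtype=bool)
        mask[0, 0, 0, 0] = mask[3, 2, 1, 0] = True
        T2 = T.copy()
        T2[mask] = 1e6  # garbage in masked cells
        F1 = cp_decompose(T, rank=2, seed=0, mask=mask)
        F2 = cp_decompose(T2, rank=2, seed=0, mask=mask)
        for a, b in zip(F1.factors, F2.factors):
            np.testing.assert_allclose(a, b, atol=1e-10)


class TestSupervisedCP:
    def test_gamma_zero_reduces_to_unsupervised(self):
        T, _ = _exact_rank((12, 5, 4, 3), 2, seed=8)
        T += 0.1 * np.random.default_rng(9).standard_normal(T.shape)
        y = np.random.default_rng(10).standard_normal(12)
        Fu = cp_decompose(T, rank=2, seed=3)
        Fs = supervised_cp(T, rank=2, sup=SupervisionSpec(target=y,
                                                          gamma=0.0),
                           seed=3)
        for a, b in zip(Fu.factors, Fs.factors):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(Fu.weights, Fs.weights)

    def test_noiseless_target_component_recovered_out_of_sample(self):
        rng = np.random.default_rng(11)
        ages = np.linspace(0.0, 1.0, 24)
        vecs = [np.abs(rng.standard_normal(d)) + 0.5 for d in (4, 3, 3)]
        T = np.einsum("i,j,k,l->ijkl", ages, *vecs)
        F = cp_decompose(T[:18], rank=1, seed=0)
        scores = project_subjects(F, T[18:])
        r = np.corrcoef(scores[:, 0], ages[18:])[0, 1]
        assert abs(r) > 0.99

    def test_supervision_finds_weak_target_component(self):
        # three strong nuisance components plus one weaker target-aligned
        # component: unsupervised rank-3 ignores the target axis, the
        # supervised factorization recovers it on held-out subjects
        rng = np.random.default_rng(12)
        n = 40
        ages = np.linspace(5.0, 84.0, n)
        a = (ages - ages.mean()) / ages.std()

        def unit(d):
            v = rng.standard_normal(d)
            return v / np.linalg.norm(v)

        comps = []
        for lam, prof in [(10.0, rng.standard_normal(n)),
                          (10.0, rng.standard_normal(n)),
                          (10.0, rng.standard_normal(n)),
                          (6.0, a)]:
            prof = (prof - prof.mean()) / prof.std()
            comps.append(lam * np.einsum("i,j,k,l->ijkl", prof, unit(6),
                                         unit(6), unit(15)))
        T = sum(comps) + 0.7 * rng.standard_normal((n, 6, 6, 15))
        Tf = FeatureTensor(values=T, mask=np.zeros(T.shape, bool),
                           labels={"subject": [str(i) for i in range(n)],
                                   "sensor": [f"s{i}" for i in range(6)],
                                   "band": [f"b{i}" for i in range(6)],
                                   "measure": [f"m{i}" for i in range(15)]})
        r_sup = nd.crossval_factor_correlation(Tf, ages, rank=3, k=5,
                                               supervised=True, seed=0)
        r_unsup = nd.crossval_factor_correlation(Tf, ages, rank=3, k=5,
                                                 supervised=False, seed=0)
        assert r_sup > 0.9
        assert r_sup > r_unsup + 0.3

    def test_invalid_supervision_rejected(self):
        with pytest.raises(ValueError):
            SupervisionSpec(target=np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            SupervisionSpec(target=np.arange(4.0), gamma=-1.0)
        cov = np.ones((6, 2))  # rank deficient
        T, _ = _exact_rank((6, 3, 3, 2), 1, seed=13)
        with pytest.raises(ValueError):
            supervised_cp(T, 1, SupervisionSpec(target=np.arange(6.0),
                                                covariates=cov))


class TestExplainedFit:
    def test_perfect_and_zero(self):
        T, facs = _exact_rank((6, 4, 3, 2), 2, seed=14)
        F = cp_decompose(T, rank=2, seed=0)
        assert explained_fit(T, F) == pytest.approx(1.0, abs=1e-6)
        zero = CPFactors(weights=np.zeros(2),
                         factors=[np.zeros((d, 2)) for d in T.shape],
                         rank=2, n_iter=0, fit=0.0, converged=True, seed=0)
        assert explained_fit(T, zero) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_norm(self):
        T, _ = _exact_rank((6, 4, 3, 2), 2, seed=15)
        noisy = T + 0.2 * np.random.default_rng(16).standard_normal(T.shape)
        F = cp_decompose(noisy, rank=2, seed=0)
        rec = reconstruct(F)
        expected = 1.0 - np.linalg.norm(noisy - rec) / np.linalg.norm(noisy)
        assert explained_fit(noisy, F) == pytest.approx(expected, abs=1e-12)

    def test_zero_tensor_rejected(self):
        T = np.zeros((4, 3, 2, 2))
        F = CPFactors(weights=np.zeros(1),
                      factors=[np.zeros((d, 1)) for d in T.shape],
                      rank=1, n_iter=0, fit=0.0, converged=True, seed=0)
        with pytest.raises(ValueError):
            explained_fit(T, F)


def test_tensor_save_load_roundtrip(tmp_path, tiny_feature_tables):
    tables, cohort = tiny_feature_tables
    T = normalize_tensor(assemble_tensor(tables, cohort))
    T.save(tmp_path / "tens")
    back = FeatureTensor.load(tmp_path / "tens")
    np.testing.assert_array_equal(back.values, T.values)
    np.testing.assert_array_equal(back.mask, T.mask)
    assert back.labels == T.labels
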