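"""Feature pipelines against hand computations and independent oracles."""

import numpy as np
import pytest

from bruteeg import (
    EpochDataset,
    FeatureMatrix,
    Normalizer,
    StateError,
    ValidationError,
    car,
    concat_all,
    csp_features,
    csp_fit,
    csp_solve,
    dwt_features,
    raw_features,
)
from bruteeg.features import ICAExtractor, PCA, FeaturePipeline, dwt_band_energies

from conftest import make_axis_dataset


def _dataset_from_trials(trials, labels=None, subjects=None, sfreq=64.0):
    trials = np.asarray(trials, float)
    n = trials.shape[0]
    return EpochDataset(
        data=trials,
        labels=labels if labels is not None else [0] * n,
        subjects=subjects if subjects is not None else [1] * n,
        sfreq=sfreq,
    )


class TestCar:
    def test_hand_computed_example(self):
        ds = _dataset_from_trials([[[1.0, 3.0], [3.0, 5.0]]])
        out = car(ds)
        np.testing.assert_allclose(out.data[0], [[-1.0, -1.0], [1.0, 1.0]])

    def test_channel_mean_is_zero_everywhere(self, small_ds):
        out = car(small_ds)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_idempotent(self, small_ds):
        once = car(small_ds)
        np.testing.assert_allclose(car(once).data, once.data, atol=1e-12)

    def test_equal_channels_vanish(self):
        ds = _dataset_from_trials([[[2.0, -1.0], [2.0, -1.0]]])
        np.testing.assert_allclose(car(ds).data, 0.0)

    def test_single_channel_rejected(self):
        ds = EpochDataset(np.zeros((1, 1, 4)), [0], [1], 1.0)
        with pytest.raises(ValidationError):
            car(ds)


class TestDwt:
    def test_haar_worked_example(self):
        """Orthonormal Haar level 1 on [1,2,3,4]: approximation
        ((1+2)/sqrt2, (3+4)/sqrt2), detail (-1/sqrt2, -1/sqrt2)."""
        coeffs, energies = dwt_band_energies([1.0, 2.0, 3.0, 4.0], "haar", 1)
        approx, detail = coeffs
        np.testing.assert_allclose(approx, [2.1213, 4.9497], atol=1e-4)
        np.testing.assert_allclose(detail, [-0.7071, -0.7071], atol=1e-4)
        assert energies[1] == pytest.approx(1.0, abs=1e-10)

    def test_constant_signal_has_zero_detail(self):
        coeffs, energies = dwt_band_energies([1.0, 1.0, 1.0, 1.0], "haar", 1)
        np.testing.assert_allclose(coeffs[1], 0.0)
        assert energies[1] == 0.0

    @pytest.mark.parametrize("wavelet", ["haar", "db4"])
    def test_parseval_energy_conservation(self, wavelet):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.standard_normal(64)
            _, energies = dwt_band_energies(x, wavelet, 3)
            assert energies.sum() == pytest.approx((x**2).sum(), rel=1e-8)

    def test_feature_layout_and_provenance(self, small_ds):
        fm = dwt_features(car(small_ds), wavelet="haar", level=2)
        # per channel: (approx + 2 detail bands) x 3 statistics
        assert fm.n_features == small_ds.n_channels * 3 * 3
        assert fm.provenance == "car_dwt"
        assert fm.feature_names[0].endswith("_a2_mean")

    def test_too_deep_level_rejected(self, tiny_ds):
        with pytest.raises(ValidationError, match="level"):
            dwt_features(tiny_ds, wavelet="haar", level=3)  # 4 samples < 2^3


class TestPca:
    def test_printed_covariance_eigenvalues(self):
        """A cloud with sample covariance [[2,1],[1,2]] has component
        variances 3 and 1 (the eigenvalues)."""
        z = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, -1.0], [-1.0, 1.0]])
        z *= np.sqrt(3) / 2  # ddof=1 covariance of z is the identity
        m = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
        x = z @ m.T
        np.testing.assert_allclose(np.cov(x.T), [[2, 1], [1, 2]], atol=1e-12)
        pca = PCA().fit(x)
        np.testing.assert_allclose(pca.explained_variance_, [3.0, 1.0], atol=1e-10)

    def test_total_variance_preserved_and_decorrelated(self, small_ds):
        x = raw_features(small_ds).values[:, :40]
        pca = PCA().fit(x)
        t = pca.transform(x)
        assert t.var(axis=0, ddof=1).sum() == pytest.approx(
            (x - x.mean(0)).var(axis=0, ddof=1).sum()
        )
        cov = np.cov(t.T)
        off = cov - np.diag(np.diag(cov))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_matches_sklearn_reference(self, small_ds):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        x = raw_features(small_ds).values[:, :30]
        ours = PCA().fit(x)
        ref = sklearn_pca(n_components=None, svd_solver="full").fit(x)
        np.testing.assert_allclose(
            ours.explained_variance_[: ref.n_components_],
            ref.explained_variance_,
            rtol=1e-8,
        )

    def test_transform_before_fit_is_state_error(self):
        with pytest.raises(StateError):
            PCA().transform(np.zeros((2, 2)))


class TestIca:
    @staticmethod
    def _laplace_trials(rng, mixing, n_trials=12, n_samples=200):
        trials = []
        sources = []
        for _ in range(n_trials):
            s = rng.laplace(size=(2, n_samples))
            s /= s.std(axis=1, keepdims=True)
            sources.append(s)
            trials.append(mixing @ s)
        return np.stack(trials), sources

    def test_identity_mixture_recovers_signed_permutation(self):
        rng = np.random.default_rng(2)
        data, _ = self._laplace_trials(rng, np.eye(2))
        ica = ICAExtractor().fit(_dataset_from_trials(data))
        prod = ica.unmixing_ @ np.eye(2)
        # each row/column has exactly one entry of magnitude ~1
        mags = np.sort(np.abs(prod).ravel())[::-1]
        assert mags[0] == pytest.approx(1.0, abs=0.1)
        assert mags[1] == pytest.approx(1.0, abs=0.1)
        assert mags[2] < 0.1 and mags[3] < 0.1

    def test_deterministic_given_fixed_internal_seed(self, small_ds):
        a = ICAExtractor().fit(small_ds).transform(small_ds)
        b = ICAExtractor().fit(small_ds).transform(small_ds)
        np.testing.assert_array_equal(a.values, b.values)

    def test_recovers_planted_nongaussian_sources(self):
        """Components of a two-source Laplace mixture correlate > 0.9 with
        one distinct true source each."""
        rng = np.random.default_rng(4)
        mixing = np.array([[2.0, 1.0], [1.0, 3.0]])
        data, sources = self._laplace_trials(rng, mixing)
        ds = _dataset_from_trials(data)
        ica = ICAExtractor().fit(ds)
        recovered = ica.unmixing_ @ np.concatenate(list(data), axis=1)
        truth = np.concatenate(sources, axis=1)
        corr = np.abs(np.corrcoef(recovered, truth)[:2, 2:])
        # best assignment: each recovered component matches a distinct source
        assert max(corr[0, 0] * corr[1, 1], corr[0, 1] * corr[1, 0]) > 0.9**2

    def test_convergence_flag_in_meta(self, small_ds):
        fm = ICAExtractor(max_iter=1).fit(small_ds).transform(small_ds)
        assert fm.meta["ica_converged"] is False
        fm2 = ICAExtractor().fit(small_ds).transform(small_ds)
        assert "ica_converged" in fm2.meta


class TestCsp:
    def test_axis_aligned_toy_eigenvalues(self):
        """diag(4,1) vs diag(1,4) class covariances: eigenvalues {0.8, 0.2},
        filters aligned with the coordinate axes."""
        ds = make_axis_dataset()
        banks = csp_fit(ds, "pairwise")
        bank = banks[0]
        assert bank.contrast == (0, 1)
        np.testing.assert_allclose(bank.eigenvalues, [0.8, 0.2], atol=1e-10)
        for col in bank.filters.T:
            col = col / np.abs(col).max()
            assert np.sort(np.abs(col))[0] < 1e-8  # one axis only

    def test_matches_brute_force_generalized_eigensolver(self):
        """csp_solve agrees with an independent dense eigensolver to 1e-10."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.standard_normal((4, 4))
            b = rng.standard_normal((4, 4))
            c1 = a @ a.T / np.trace(a @ a.T)
            c2 = b @ b.T / np.trace(b @ b.T)
            evals, evecs = csp_solve(c1, c2)
            # oracle: plain eig of (C1+C2)^-1 C1
            ref = np.sort(np.linalg.eigvals(np.linalg.inv(c1 + c2) @ c1).real)[::-1]
            np.testing.assert_allclose(evals, ref, atol=1e-10)
            # eigenvector residuals
            for lam, w in zip(evals, evecs.T):
                np.testing.assert_allclose(c1 @ w, lam * (c1 + c2) @ w, atol=1e-10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((3, 3))
        b = rng.standard_normal((3, 3))
        c1 = a @ a.T / np.trace(a @ a.T)
        c2 = b @ b.T / np.trace(b @ b.T)
        e12, _ = csp_solve(c1, c2)
        e21, _ = csp_solve(c2, c1)
        np.testing.assert_allclose(np.sort(e12), np.sort(1 - e21), atol=1e-10)

    def test_identical_covariances_give_half(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((3, 3))
        c = a @ a.T / np.trace(a @ a.T)
        evals, _ = csp_solve(c, c.copy())
        np.testing.assert_allclose(evals, 0.5, atol=1e-10)

    def test_contrast_counts_and_feature_widths(self, small_ds):
        pair_banks = csp_fit(small_ds, "pairwise", n_keep=4)
        ova_banks = csp_fit(small_ds, "one_vs_all", n_keep=4)
        assert len(pair_banks) == 6 and len(ova_banks) == 4
        assert csp_features(small_ds, pair_banks).n_features == 24
        assert csp_features(small_ds, ova_banks).n_features == 16
        assert csp_features(small_ds, pair_banks).provenance == "csp_pair"
        assert csp_features(small_ds, ova_banks).provenance == "csp_ova"

    def test_planted_variance_separates_log_features(self):
        """On the diag(4,1)/diag(1,4) toy, class-0 trials score higher on the
        first retained filter than class-1 trials."""
        ds = make_axis_dataset()
        banks = csp_fit(ds, "pairwise", n_keep=2)
        fm = csp_features(ds, banks)
        class0 = fm.values[fm.labels == 0, 0].mean()
        class1 = fm.values[fm.labels == 1, 0].mean()
        assert class0 > class1

    def test_eigenvalues_sorted_descending_in_unit_interval(self, small_ds):
        for bank in csp_fit(small_ds, "pairwise"):
            assert (np.diff(bank.eigenvalues) <= 1e-12).all()
            assert bank.eigenvalues.min() >= 0 and bank.eigenvalues.max() <= 1


class TestConcatAll:
    @pytest.fixture()
    def parts(self, small_ds):
        pipe = FeaturePipeline("all").fit(small_ds)
        from bruteeg.features import ALL_ORDER

        sub_parts = []
        for method in ALL_ORDER:
            p = FeaturePipeline(method).fit(small_ds)
            sub_parts.append(p.transform(small_ds))
        return sub_parts

    def test_widths_add_and_rows_align(self, parts):
        out = concat_all(parts)
        assert out.n_features == sum(p.n_features for p in parts)
        np.testing.assert_array_equal(
            out.values[0], np.concatenate([p.values[0] for p in parts])
        )
        assert out.provenance == "all"

    def test_wrong_order_rejected(self, parts):
        with pytest.raises(ValidationError, match="provenance"):
            concat_all(parts[::-1])

    def test_row_mismatch_rejected(self, parts):
        short = parts[0].select(np.arange(parts[0].n_trials - 1))
        with pytest.raises(ValidationError):
            concat_all([short] + parts[1:])


class TestNormalizer:
    def test_worked_example(self):
        fm = FeatureMatrix(np.array([[2.0], [4.0], [6.0]]), [0, 1, 2], [1, 1, 1], "raw")
        out = Normalizer().fit(fm).apply(fm)
        np.testing.assert_allclose(out.values[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_constant_column_maps_to_zero(self):
        vals = np.column_stack([np.ones(4), np.arange(4.0)])
        fm = FeatureMatrix(vals, [0, 1, 2, 3], [1, 1, 1, 1], "raw")
        out = Normalizer().fit(fm).apply(fm)
        np.testing.assert_array_equal(out.values[:, 0], 0.0)

    def test_train_columns_standardised(self, small_ds):
        fm = raw_features(small_ds)
        out = Normalizer().fit(fm).apply(fm)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-10)
        sd = out.values.std(axis=0)
        np.testing.assert_allclose(sd[sd > 0], 1.0, atol=1e-10)

    def test_width_mismatch_rejected(self, small_ds):
        nz = Normalizer().fit(raw_features(small_ds))
        narrow = FeatureMatrix(np.zeros((2, 3)), [0, 1], [1, 1], "raw")
        with pytest.raises(ValidationError):
            nz.apply(narrow)


class TestLeakageGuards:
    def test_fitting_set_matters(self, small_ds):
        """Fitting on train+test rows yields different transforms than
        fitting on train only (the fit genuinely depends on its input)."""
        half = small_ds.select(np.arange(small_ds.n_trials // 2))
        pipe_half = FeaturePipeline("csp_pair").fit(half)
        pipe_full = FeaturePipeline("csp_pair").fit(small_ds)
        a = pipe_half.transform(half).values
        b = pipe_full.transform(half).values
        assert not np.allclose(a, b)

    @pytest.mark.parametrize("method", ["pca", "ica", "csp_pair", "car_dwt"])
    def test_perturbing_unseen_rows_leaves_fit_unchanged(self, small_ds, method):
        train = small_ds.select(np.arange(0, small_ds.n_trials, 2))
        probe = small_ds.select(np.arange(0, 8))
        a = FeaturePipeline(method).fit(train).transform(probe).values
        perturbed = small_ds.select(np.arange(1, small_ds.n_trials, 2))
        perturbed.data += 100.0  # rows the pipeline never saw
        b = FeaturePipeline(method).fit(train).transform(probe).values
        np.testing.assert_array_equal(a, b)
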