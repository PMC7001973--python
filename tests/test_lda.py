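"""Linear discriminant lifestyle models: fit, posteriors, bootstrap, morphospace."""

import math

import numpy as np
import pytest
from scipy import stats

from clawcurve.geometry import ClawMeasures
from clawcurve.io import Category, Dataset, Pes, SpecimenRecord
from clawcurve.lda import (
    DegenerateDataError,
    LifestyleResults,
    ModelMismatchError,
    classify_fossil_set,
    confidence_ellipse,
    fit_lda,
)
from clawcurve.simulate import default_group_specs, generate_extant, generate_fossils


def dataset_from_arrays(groups, metrics=("IU", "OU")):
    """groups: {Category: (n, p) array of angles} -> Dataset."""
    records = []
    i = 0
    for cat, X in groups.items():
        for row in np.atleast_2d(X):
            i += 1
            angles = dict(zip(metrics, (float(v) for v in row)))
            records.append(
                SpecimenRecord(
                    taxon=f"T {i}", specimen_id=f"S{i}", pes=Pes.LEFT,
                    category=cat, body_mass_g=100.0,
                    measures=ClawMeasures(**angles),
                )
            )
    return Dataset(records)


class TestFit:
    def test_two_separated_univariate_classes_single_axis(self, rng):
        g = {
            Category.TERRESTRIAL: np.abs(rng.normal(40, 1, size=(200, 1))) ,
            Category.SCANSORIAL: np.abs(rng.normal(140, 1, size=(200, 1))),
        }
        res = fit_lda(dataset_from_arrays(g, metrics=("IU",)), ["IU"])
        assert res.params.n_axes == 1
        assert np.allclose(res.params.proportion_of_trace, [1.0])

    def test_degenerate_collinear_metrics_rejected(self, rng):
        iu = rng.normal(60, 10, size=40)
        g = {
            Category.TERRESTRIAL: np.column_stack([iu[:20], iu[:20] * 2.0]),
            Category.SCANSORIAL: np.column_stack([iu[20:], iu[20:] * 2.0]),
        }
        with pytest.raises(DegenerateDataError):
            fit_lda(dataset_from_arrays(g), ["IU", "OU"])

    def test_scalings_sphere_within_class_covariance(self, dataset):
        res = fit_lda(dataset, ["IU", "OU", "IS2", "OS"])
        S, W = res.params.scalings, res.params.pooled_cov
        assert np.allclose(S.T @ W @ S, np.eye(res.params.n_axes), atol=1e-8)

    def test_proportion_of_trace_sorted_and_normalized(self, dataset):
        res = fit_lda(dataset, ["IU", "OU", "IS2", "OS"])
        prop = res.params.proportion_of_trace
        assert math.isclose(prop.sum(), 1.0, abs_tol=1e-12)
        assert np.all(np.diff(prop) <= 1e-12)
        assert res.params.n_axes == 3  # min(4 categories - 1, 4 metrics)

    def test_subspace_matches_sklearn(self, dataset):
        """Independent oracle: the discriminant subspace agrees with
        scikit-learn's eigen-solver LDA (principal angles ~ 0)."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        res = fit_lda(dataset, ["IU", "OU", "IS2", "OS"])
        df = dataset.subset_complete(["IU", "OU", "IS2", "OS"]).to_dataframe()
        X = df[["IU", "OU", "IS2", "OS"]].to_numpy()
        y = df["category"].to_numpy()
        sk = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        qa, _ = np.linalg.qr(res.params.scalings)
        qb, _ = np.linalg.qr(sk.scalings_[:, : res.params.n_axes])
        sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
        principal_angles = np.arccos(np.clip(sv, -1, 1))
        assert principal_angles.max() < 1e-6

    def test_priors_frequency_vs_uniform(self, rng):
        g = {
            Category.TERRESTRIAL: rng.normal([40, 60], 5, size=(40, 2)),
            Category.SCANSORIAL: rng.normal([90, 110], 5, size=(10, 2)),
        }
        data = dataset_from_arrays(g)
        freq = fit_lda(data, ["IU", "OU"]).params.priors
        assert np.allclose(freq, [0.8, 0.2])
        unif = fit_lda(data, ["IU", "OU"], priors="uniform").params.priors
        assert np.allclose(unif, [0.5, 0.5])


class TestPredict:
    def test_posteriors_sum_to_one_and_argmax(self, dataset):
        res = fit_lda(dataset, ["IU", "OU"])
        for rec in dataset.records[::7]:
            r = res.predict(rec.measures)
            assert math.isclose(sum(r.posteriors.values()), 1.0, abs_tol=1e-9)
            assert r.predicted == max(r.posteriors, key=r.posteriors.get)

    def test_class_mean_wins_when_separated(self, rng):
        g = {
            Category.TERRESTRIAL: rng.normal([40, 60], 3, size=(30, 2)),
            Category.PERCHING: rng.normal([60, 85], 3, size=(30, 2)),
            Category.SCANSORIAL: rng.normal([90, 115], 3, size=(30, 2)),
        }
        res = fit_lda(dataset_from_arrays(g), ["IU", "OU"], priors="uniform")
        for k, cat in enumerate(res.params.categories):
            m = res.params.class_means[k]
            r = res.predict(ClawMeasures(IU=m[0], OU=m[1]))
            assert r.predicted is cat
            assert r.posteriors[cat] > max(
                v for c, v in r.posteriors.items() if c is not cat
            )

    def test_identical_classes_uniform_posteriors(self, rng):
        X = rng.normal([60, 85], 8, size=(25, 2))
        g = {
            Category.TERRESTRIAL: X,
            Category.PERCHING: X,
            Category.PREDATORY: X,
            Category.SCANSORIAL: X,
        }
        res = fit_lda(dataset_from_arrays(g), ["IU", "OU"], priors="uniform")
        r = res.predict(ClawMeasures(IU=70.0, OU=90.0))
        assert np.allclose(list(r.posteriors.values()), 0.25, atol=1e-12)

    def test_two_class_univariate_midpoint_rule(self, rng):
        """With equal priors, one metric and two classes, the decision
        boundary is the midpoint of the class means (closed form)."""
        g = {
            Category.TERRESTRIAL: np.abs(rng.normal(40, 6, size=(50, 1))),
            Category.SCANSORIAL: np.abs(rng.normal(100, 6, size=(50, 1))),
        }
        res = fit_lda(dataset_from_arrays(g, metrics=("IU",)), ["IU"], priors="uniform")
        mid = float(res.params.class_means.mean())
        lo = res.predict(ClawMeasures(IU=mid - 0.5, OU=0.0))
        hi = res.predict(ClawMeasures(IU=mid + 0.5, OU=0.0))
        assert lo.predicted is Category.TERRESTRIAL
        assert hi.predicted is Category.SCANSORIAL
        at = res.predict(ClawMeasures(IU=mid, OU=0.0))
        assert math.isclose(at.posteriors[Category.TERRESTRIAL], 0.5, abs_tol=1e-9)

    def test_location_invariance(self, dataset):
        """Adding a constant to every metric shifts means and data together:
        posteriors are unchanged (shared-covariance LDA is location
        invariant)."""
        res = fit_lda(dataset, ["IU", "OU"])
        shift = 7.5
        shifted = Dataset(
            [
                SpecimenRecord(
                    r.taxon, r.specimen_id, r.pes, r.category, r.body_mass_g,
                    ClawMeasures(IU=r.measures.IU + shift, OU=r.measures.OU + shift),
                )
                for r in dataset.records
            ]
        )
        res_s = fit_lda(shifted, ["IU", "OU"])
        for rec in dataset.records[::11]:
            p0 = res.predict(rec.measures).posteriors
            p1 = res_s.predict(
                ClawMeasures(IU=rec.measures.IU + shift, OU=rec.measures.OU + shift)
            ).posteriors
            for c in p0:
                assert math.isclose(p0[c], p1[c], abs_tol=1e-9)

    def test_posteriors_match_sklearn(self, dataset):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        res = fit_lda(dataset, ["IU", "OU"])
        df = dataset.subset_complete(["IU", "OU"]).to_dataframe()
        X = df[["IU", "OU"]].to_numpy()
        y = df["category"].to_numpy()
        sk = LinearDiscriminantAnalysis(solver="svd", store_covariance=True).fit(X, y)
        ours = res.posterior_matrix(X)
        cols = [list(sk.classes_).index(c.value) for c in res.params.categories]
        theirs = sk.predict_proba(X)[:, cols]
        # sklearn pools with divisor N (biased); agreement is close, not exact
        assert np.abs(ours - theirs).max() < 5e-3

    def test_missing_metric_raises_model_mismatch(self, dataset):
        res = fit_lda(dataset, ["IU", "OU", "IS2", "OS"])
        with pytest.raises(ModelMismatchError, match="IS2"):
            res.predict(ClawMeasures(IU=50.0, OU=70.0))

    def test_save_load_roundtrip(self, dataset, tmp_path):
        res = fit_lda(dataset, ["IU", "OU"])
        res.save(tmp_path / "m.json")
        back = LifestyleResults.load(tmp_path / "m.json")
        rec = dataset.records[3].measures
        assert res.predict(rec).posteriors == back.predict(rec).posteriors


class TestProjection:
    def test_grand_mean_maps_to_origin(self, dataset):
        res = fit_lda(dataset, ["IU", "OU"])
        z = res.project(res.params.grand_mean[None, :])
        assert np.allclose(z, 0.0, atol=1e-9)

    def test_scores_reproduce_mahalanobis_distances(self, dataset):
        """With as many discriminant axes as metrics, Euclidean distances of
        the scores equal pooled-covariance Mahalanobis distances (sphering),
        checked against the brute-force quadratic form."""
        res = fit_lda(dataset, ["IU", "OU"])  # 2 metrics, 4 classes: 2 axes
        assert res.params.n_axes == len(res.params.metrics)
        df = dataset.subset_complete(["IU", "OU"]).to_dataframe()
        X = df[["IU", "OU"]].to_numpy()[:20]
        z = res.project(X)
        w_inv = np.linalg.inv(res.params.pooled_cov)
        for i in range(5):
            d_full = ((X - X[i]) @ w_inv * (X - X[i])).sum(axis=1)
            d_proj = ((z - z[i]) ** 2).sum(axis=1)
            assert np.allclose(d_full, d_proj, atol=1e-8)


class TestConfidenceEllipse:
    def test_isotropic_cloud_radius(self, rng):
        pts = rng.normal(size=(20000, 2))
        e = confidence_ellipse(pts, level=0.95)
        expected = math.sqrt(stats.chi2.ppf(0.95, df=2))  # ~2.4477
        assert abs(e.semi_axes[0] - expected) < 0.06
        assert abs(e.semi_axes[1] - expected) < 0.06

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(DegenerateDataError):
            confidence_ellipse(pts)

    def test_level_zero_shrinks_to_centroid(self, rng):
        pts = rng.normal(size=(50, 2)) + [3.0, -2.0]
        e = confidence_ellipse(pts, level=0.0)
        assert e.semi_axes == (0.0, 0.0)
        assert np.allclose(e.center, pts.mean(axis=0))

    def test_coverage_close_to_nominal(self, rng):
        pts = rng.multivariate_normal([0, 0], [[2.0, 0.7], [0.7, 1.0]], size=4000)
        e = confidence_ellipse(pts, level=0.95)
        phi = math.radians(e.rotation_deg)
        R = np.array([[math.cos(phi), math.sin(phi)], [-math.sin(phi), math.cos(phi)]])
        local = (pts - np.array(e.center)) @ R.T
        inside = (local[:, 0] / e.semi_axes[0]) ** 2 + (
            local[:, 1] / e.semi_axes[1]
        ) ** 2 <= 1.0
        assert abs(inside.mean() - 0.95) < 0.015


class TestBootstrap:
    def test_perfect_separation_accuracy_one(self, rng):
        g = {
            Category.TERRESTRIAL: rng.normal([30, 50], 0.5, size=(25, 2)),
            Category.PERCHING: rng.normal([80, 100], 0.5, size=(25, 2)),
            Category.SCANSORIAL: rng.normal([130, 150], 0.5, size=(25, 2)),
        }
        res = fit_lda(dataset_from_arrays(g), ["IU", "OU"])
        acc = res.bootstrap_accuracy(n_iterations=100, seed=1)
        assert acc.total_accuracy == 1.0
        assert all(v == 1.0 for v in acc.per_class_accuracy.values())

    def test_shuffled_labels_chance_level(self, dataset, rng):
        """Randomly permuted labels on 4 balanced classes give ~25% accuracy."""
        recs = dataset.records
        perm = rng.permutation(len(recs))
        shuffled = Dataset(
            [
                SpecimenRecord(
                    r.taxon, r.specimen_id, r.pes, recs[j].category, r.body_mass_g,
                    r.measures,
                )
                for r, j in zip(recs, perm)
            ]
        )
        res = fit_lda(shuffled, ["IU", "OU"])
        acc = res.bootstrap_accuracy(n_iterations=300, seed=2)
        assert abs(acc.total_accuracy - 0.25) < 0.08

    def test_seeded_reproducibility(self, dataset):
        res = fit_lda(dataset, ["IU", "OU"])
        a = res.bootstrap_accuracy(n_iterations=50, seed=9)
        b = res.bootstrap_accuracy(n_iterations=50, seed=9)
        assert a.total_accuracy == b.total_accuracy
        assert a.per_class_accuracy == b.per_class_accuracy


class TestParameterRecovery:
    def test_class_mean_error_shrinks_with_n(self):
        """Estimated class means converge toward generator truth ~ 1/sqrt(n)."""
        errors = []
        for n in (50, 200, 800):
            specs = default_group_specs(n_per_group=n)
            data = generate_extant(specs, seed=99)
            res = fit_lda(data, ["IU", "OU"])
            err = 0.0
            for spec in specs:
                k = res.params.categories.index(spec.category)
                truth = np.array(spec.mean_vector[:2])
                # zero-inflation and truncation shift terrestrial IU; compare OU only
                err += abs(res.params.class_means[k][1] - truth[1])
            errors.append(err)
        assert errors[2] < errors[0]


class TestFossilClassification:
    def test_m1_only_without_sheath(self, dataset, fossil_sample):
        fossils, _ = fossil_sample
        m1 = fit_lda(dataset, ["IU", "OU"])
        m2 = fit_lda(dataset, ["IU", "OU", "IS2", "OS"])
        table = classify_fossil_set(m1, m2, fossils)
        assert len(table) == len(fossils)
        for row, f in zip(table.itertuples(), fossils):
            m1_post = [getattr(row, f"M1_{c.value}") for c in m1.params.categories]
            assert math.isclose(sum(m1_post), 1.0, abs_tol=1e-9)
            if f.has_sheath:
                m2_post = [getattr(row, f"M2_{c.value}") for c in m2.params.categories]
                assert math.isclose(sum(m2_post), 1.0, abs_tol=1e-9)
            else:
                assert row.M2_predicted == ""

    def test_recovery_beats_chance(self, dataset, fossil_sample):
        fossils, truths = fossil_sample
        m1 = fit_lda(dataset, ["IU", "OU"])
        table = classify_fossil_set(m1, None, fossils)
        rate = np.mean(
            [p == t.value for p, t in zip(table["M1_predicted"], truths)]
        )
        assert rate > 0.5  # four balanced classes: chance is 0.25

    def test_recovery_monotone_in_separation(self):
        """Fossil category recovery improves as group means separate."""
        rates = []
        for sep in (0.4, 1.0, 1.8):
            specs = default_group_specs(n_per_group=40, separation=sep)
            data = generate_extant(specs, seed=31)
            fossils, truths = generate_fossils(
                specs, n_per_category=25, sheath_missing_prob=1.0, seed=32
            )
            m1 = fit_lda(data, ["IU", "OU"])
            table = classify_fossil_set(m1, None, fossils)
            rates.append(
                np.mean([p == t.value for p, t in zip(table["M1_predicted"], truths)])
            )
        assert rates[0] < rates[1] < rates[2]

    def test_m1_must_be_bone_model(self, dataset, fossil_sample):
        fossils, _ = fossil_sample
        m2 = fit_lda(dataset, ["IU", "OU", "IS2", "OS"])
        with pytest.raises(ValueError, match=r"IU, OU"):
            classify_fossil_set(m2, None, fossils)
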