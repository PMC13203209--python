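import numpy as np
import pytest

from kdeknn import (
    ConvergenceError,
    DataError,
    GeneratorConfig,
    TabularDataset,
    dcr_synthetic,
    export_synthetic,
    fit_kde,
    fit_knn,
    fit_preprocessor,
    generate,
    partition_by_class,
    predict,
    read_csv_dataset,
    sample_kde,
)


def _clusters(n_per_class=60, sep=20.0, d=2, seed=0) -> TabularDataset:
    """Two tight, far-separated Gaussian clusters — misclassification is
    effectively impossible."""
    rng = np.random.default_rng(seed)
    neg = rng.normal(0.0, 1.0, (n_per_class, d))
    pos = rng.normal(sep, 1.0, (n_per_class, d))
    values = np.concatenate([neg, pos])
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    return TabularDataset(values, labels, [f"f{j}" for j in range(d)])


class TestPartition:
    def test_sizes_and_conservation(self):
        ds = TabularDataset(np.arange(6, dtype=float).reshape(3, 2),
                            np.array([1, 0, 1]), ["a", "b"])
        pos, neg = partition_by_class(ds)
        assert pos.n == 2 and neg.n == 1
        merged = {tuple(r) for r in np.concatenate([pos.values, neg.values])}
        assert merged == {tuple(r) for r in ds.values}

    def test_single_class_rejected(self):
        ds = TabularDataset(np.zeros((3, 1)), np.ones(3, dtype=int), ["a"])
        with pytest.raises(DataError):
            partition_by_class(ds)

    def test_clinical_fixture_imbalance(self, clinical_fixture):
        pos, neg = partition_by_class(clinical_fixture)
        assert pos.n / clinical_fixture.n == pytest.approx(296 / 1275, abs=1e-9)


class TestGenerate:
    def test_separated_clusters_fast_convergence(self):
        train = _clusters()
        config = GeneratorConfig(sigma_multiplier=0.0, target_positive=100,
                                 target_negative=100, seed=1)
        synthetic, report = generate(train, config)
        assert report.iterations == 1  # batch = target, nothing rejected
        assert report.positive.rejected_utility == 0
        assert report.negative.rejected_utility == 0
        assert synthetic.labels.sum() == 100

    def test_impossible_threshold_raises_with_report(self):
        train = _clusters(n_per_class=30)
        config = GeneratorConfig(sigma_multiplier=1e6, max_iterations=3, seed=2,
                                 target_positive=10, target_negative=10)
        with pytest.raises(ConvergenceError) as err:
            generate(train, config)
        report = err.value.report
        assert report is not None and report.iterations == 3
        assert report.positive.accepted == 0

    def test_ablation_identity_matches_raw_kde_draws(self):
        train = _clusters(seed=3)
        config = GeneratorConfig(utility_validation=False,
                                 privacy_validation=False,
                                 target_positive=50, target_negative=70, seed=9)
        synthetic, report = generate(train, config)
        pos, neg = partition_by_class(train)
        kde_pos = fit_kde(pos.values)
        kde_neg = fit_kde(neg.values)
        expected_pos = sample_kde(kde_pos, 50, np.random.default_rng([9, 1]))
        expected_neg = sample_kde(kde_neg, 70, np.random.default_rng([9, 0]))
        np.testing.assert_array_equal(synthetic.values[:50], expected_pos)
        np.testing.assert_array_equal(synthetic.values[50:], expected_neg)

    def test_missing_values_rejected(self):
        train = _clusters()
        train.values[0, 0] = np.nan
        with pytest.raises(DataError):
            generate(train, GeneratorConfig())


class TestDefaultFixtureRun:
    """Invariants of a full run on the clinical-shaped fixture."""

    def test_exact_class_balance(self, generated_default):
        _, config, synthetic, _ = generated_default
        assert (synthetic.labels == 1).sum() == config.target_positive
        assert (synthetic.labels == 0).sum() == config.target_negative

    def test_every_record_passes_posthoc_validation(self, generated_default):
        train_std, config, synthetic, _ = generated_default
        model = fit_knn(train_std, config.k_neighbors)
        np.testing.assert_array_equal(predict(model, synthetic.values),
                                      synthetic.labels)

    def test_privacy_floor(self, generated_default):
        train_std, _, synthetic, report = generated_default
        min_dcr = dcr_synthetic(synthetic.values, train_std.values).distances.min()
        assert min_dcr >= report.threshold

    def test_accounting_conservation(self, generated_default):
        _, _, _, report = generated_default
        for counts in (report.positive, report.negative):
            assert counts.drawn == (counts.accepted + counts.rejected_utility
                                    + counts.rejected_privacy)

    def test_rerun_is_bit_identical(self, generated_default):
        train_std, config, synthetic, report = generated_default
        synthetic2, report2 = generate(train_std, config)
        np.testing.assert_array_equal(synthetic.values, synthetic2.values)
        np.testing.assert_array_equal(synthetic.labels, synthetic2.labels)
        assert report.to_dict() == report2.to_dict()


def test_distribution_recovery_without_validation(standardized_split):
    """With both filters off, per-class synthetic means track the class
    support means (mixture mean identity, Monte-Carlo tolerance)."""
    train_std, _, _ = standardized_split
    config = GeneratorConfig(utility_validation=False, privacy_validation=False,
                             target_positive=2000, target_negative=2000, seed=3)
    synthetic, _ = generate(train_std, config)
    for label in (0, 1):
        real = train_std.values[train_std.labels == label]
        syn = synthetic.values[synthetic.labels == label]
        h = fit_kde(real).h
        se = np.sqrt((real.var(axis=0, ddof=1) + h**2) / syn.shape[0])
        assert (np.abs(syn.mean(axis=0) - real.mean(axis=0)) < 3.5 * se).mean() > 0.9


def test_acceptance_rate_non_increasing_in_sigma_multiplier():
    train = _clusters(n_per_class=80, sep=8.0, d=3, seed=5)
    rates = []
    for mult in (0.0, 0.5, 1.0, 2.0):
        config = GeneratorConfig(sigma_multiplier=mult, target_positive=60,
                                 target_negative=60, max_iterations=200, seed=11)
        try:
            _, report = generate(train, config)
        except ConvergenceError as err:
            report = err.value if not hasattr(err, "report") else err.report
        drawn = report.positive.drawn + report.negative.drawn
        accepted = report.positive.accepted + report.negative.accepted
        rates.append(accepted / drawn)
    assert all(a >= b - 1e-12 for a, b in zip(rates, rates[1:]))


def test_export_round_trip(tmp_path, standardized_split, generated_default):
    _, _, pre = standardized_split
    _, _, synthetic, _ = generated_default
    path = tmp_path / "synthetic.csv"
    export_synthetic(synthetic, pre, path)
    back = read_csv_dataset(path, "label", 1)
    restd = pre.apply(back)
    np.testing.assert_allclose(restd.values, synthetic.values, atol=1e-10)
    assert (back.labels == 1).sum() == (synthetic.labels == 1).sum()
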