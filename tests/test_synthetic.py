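"""Synthetic-data generators: exact labels, planted motifs, effect sizes."""

import numpy as np
import pytest

from crrpred import nn
from crrpred.encoding import one_hot_batch
from crrpred.evaluation import auroc
from crrpred.models import build_fixed_ffnn, train
from crrpred.regions import ClassLabel, label_region
from crrpred.synthetic import (
    SyntheticSpec, generate_dataset, generate_features, generate_regions,
    generate_sequences, benchmark_spec,
)


class TestSpecValidation:
    def test_imbalance_arithmetic(self):
        spec = benchmark_spec(n_total=2100, imbalance_ratio=20)
        assert spec.class_counts == {"AE": 100, "IE": 2000}

    def test_invalid_pwm_rejected(self):
        bad = np.full((8, 4), 0.3)
        with pytest.raises(ValueError):
            SyntheticSpec(class_counts={"AE": 1}, pwm=bad)
        with pytest.raises(ValueError):
            SyntheticSpec(class_counts={"AE": 1}, pwm=np.full((3, 4), 0.25))

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            benchmark_spec(effect_size=-1.0)


class TestGenerateRegions:
    def test_label_round_trip_is_exact(self):
        spec = SyntheticSpec(
            class_counts={"AE": 10, "IE": 30, "AP": 5, "IP": 5, "AX": 3,
                          "IX": 3, "UK": 4},
            seed=2,
        )
        regions = generate_regions(spec)
        assert len(regions) == 60
        for r in regions:
            assert label_region(r.kind, r.evidence, "hg19") is r.label

    def test_windows_non_overlapping_fixed_width(self):
        regions = generate_regions(benchmark_spec(n_total=50, seed=1))
        spans = sorted((r.start, r.end) for r in regions)
        assert all(e - s == 200 for s, e in spans)
        assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))

    def test_intermediate_promoter_tpm_is_undefined_on_hg19(self):
        # evidence forced into (0, 5] must label UNDEFINED under the hg19 rule
        for tpm in (0.5, 3.0, 5.0):
            assert label_region("promoter", tpm, "hg19") is ClassLabel.UNDEFINED

    def test_chromosome_overflow_rejected(self):
        spec = benchmark_spec(n_total=100, chrom_length=1000)
        with pytest.raises(ValueError):
            generate_regions(spec)

    def test_bit_reproducible(self):
        a = generate_regions(benchmark_spec(seed=5, n_total=100))
        b = generate_regions(benchmark_spec(seed=5, n_total=100))
        assert a == b


class TestGenerateSequences:
    def test_certain_embedding_plants_motif_in_every_positive(self):
        spec = benchmark_spec(n_total=200, embed_prob=1.0, seed=3)
        labels = ["AE"] * 50 + ["IE"] * 150
        records = generate_sequences(labels, spec)
        for rec in records:
            if rec.label == "AE":
                assert 0 <= rec.motif_start <= 200 - len(spec.pwm)
            else:
                assert rec.motif_start == -1

    def test_zero_embedding_plants_nothing(self):
        spec = benchmark_spec(n_total=100, embed_prob=0.0, seed=3)
        records = generate_sequences(["AE"] * 50, spec)
        assert all(rec.motif_start == -1 for rec in records)

    def test_background_frequencies_near_uniform(self):
        spec = benchmark_spec(n_total=100, embed_prob=0.0, seed=4)
        records = generate_sequences(["IE"] * 500, spec)
        joined = "".join(rec.sequence for rec in records)
        n = len(joined)
        sigma = np.sqrt(0.25 * 0.75 / n)
        for base in "ACGT":
            assert abs(joined.count(base) / n - 0.25) < 3 * sigma + 1e-3

    def test_motif_longer_than_window_rejected(self):
        spec = benchmark_spec(window_length=200)
        bad = SyntheticSpec(
            class_counts=spec.class_counts, window_length=7,
            pwm=spec.pwm, embed_prob={"AE": 1.0},
        )
        with pytest.raises(ValueError):
            generate_sequences(["AE"], bad)

    def test_no_motif_means_classes_indistinguishable(self):
        """Without a planted motif a sequence model scores at chance."""
        aurocs = []
        for seed in range(3):
            spec = benchmark_spec(n_total=300, imbalance_ratio=1.0,
                                   embed_prob=0.0, seed=seed, window_length=60)
            _, seqs, _, y = generate_dataset(spec)
            x = one_hot_batch([r.sequence for r in seqs], 60)
            perm = np.random.default_rng(seed).permutation(len(y))
            x, y = x[perm], y[perm]
            rng = np.random.default_rng(seed)
            model = nn.Sequential(
                [nn.Conv1D(4, 8, 8, rng), nn.ReLU(), nn.MaxPool1D(60),
                 nn.Flatten(), nn.Dense(8, 1, rng), nn.Sigmoid()], (60, 4))
            nn.train_network(model, nn.Nadam(0.01), x[:240], y[:240],
                             batch_size=32, max_epochs=10, seed=seed)
            aurocs.append(auroc(y[240:], model.predict(x[240:])))
        assert 0.35 <= np.mean(aurocs) <= 0.65


class TestGenerateFeatures:
    def test_shape_single_sample_per_class(self):
        spec = benchmark_spec()
        table = generate_features(["AE", "IE"], spec)
        assert table.shape == (2, spec.n_features)

    def test_effect_shifts_informative_features_only(self):
        spec = benchmark_spec(n_total=4000, effect_size=2.0, seed=6)
        labels = ["AE"] * 2000 + ["IE"] * 2000
        table = generate_features(labels, spec)
        pos = table.iloc[:2000]
        neg = table.iloc[2000:]
        shifts = (pos.mean() - neg.mean()).to_numpy()
        assert np.allclose(shifts[: spec.n_informative], 2.0, atol=0.15)
        assert np.allclose(shifts[spec.n_informative:], 0.0, atol=0.15)

    def test_zero_effect_mostly_non_significant(self):
        from scipy import stats
        spec = benchmark_spec(n_total=2000, effect_size=0.0, seed=7,
                               n_features=50, n_informative=25)
        labels = ["AE"] * 1000 + ["IE"] * 1000
        table = generate_features(labels, spec)
        pvals = [
            stats.ttest_ind(table.iloc[:1000, j], table.iloc[1000:, j]).pvalue
            for j in range(50)
        ]
        assert np.mean(np.array(pvals) > 0.01) >= 0.9

    def test_strong_effect_yields_high_validation_auroc(self):
        """Effect size 2 on a 2000-sample task is nearly separable."""
        scores = []
        for seed in range(5):
            spec = benchmark_spec(n_total=2000, effect_size=2.0, seed=seed)
            _, _, features, y = generate_dataset(spec)
            x = features.to_numpy(np.float32)
            perm = np.random.default_rng(seed).permutation(len(y))
            x, y = x[perm], y[perm]
            model, settings = build_fixed_ffnn(x.shape[1], seed=seed)
            train(model, settings, x[:1600], y[:1600], seed=seed, max_epochs=20)
            scores.append(auroc(y[1600:], model.predict(x[1600:])))
        assert np.mean(scores) > 0.95


class TestEffectMonotonicity:
    def test_mean_auroc_increases_with_effect_size(self):
        """Separability rises monotonically with the planted effect."""
        means = []
        for effect in (0.25, 1.0, 2.0):
            scores = []
            for seed in range(10):
                spec = benchmark_spec(n_total=600, imbalance_ratio=3.0,
                                       effect_size=effect, seed=100 + seed)
                _, _, features, y = generate_dataset(spec)
                x = features.to_numpy(np.float32)
                perm = np.random.default_rng(seed).permutation(len(y))
                x, y = x[perm], y[perm]
                model, settings = build_fixed_ffnn(x.shape[1], seed=seed)
                train(model, settings, x[:480], y[:480], seed=seed, max_epochs=15)
                scores.append(auroc(y[480:], model.predict(x[480:])))
            means.append(np.mean(scores))
        assert means[0] <= means[1] <= means[2]


class TestDeterminism:
    def test_all_generators_bit_reproducible(self):
        spec = benchmark_spec(n_total=100, seed=9)
        r1, s1, f1, y1 = generate_dataset(spec)
        r2, s2, f2, y2 = generate_dataset(spec)
        assert r1 == r2
        assert s1 == s2
        assert f1.equals(f2)
        assert np.array_equal(y1, y2)
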