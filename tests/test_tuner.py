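"""Embedding-similarity tuning and few-shot segmenter adaptation."""

import numpy as np
import pytest
from scipy import ndimage

from filasim.dataset_io import generate_sample
from filasim.parameters import SearchSpace, default_theta
from filasim.predictions import PredictionSet
from filasim.tuner import (AdaptationResult, FeatureEmbedding, ReferenceSet,
                           TunerConfig, adapt_segmenter, cosine_similarity,
                           objective, save_trials, tune)


class MeanIntensityEmbedding:
    """Toy backend: [1, mean] plus a coarse histogram — cosine similarity
    varies smoothly and unimodally in the background level."""

    name = "mean-intensity"
    deterministic = True

    def embed(self, image):
        gray = image.mean(axis=2) if image.ndim == 3 else image
        hist, _ = np.histogram(gray, bins=8, range=(0, 1))
        return np.concatenate([[1.0, gray.mean()], hist / max(hist.sum(), 1)])


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        v = rng.normal(size=16)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_antiparallel_is_minus_one(self, rng):
        v = rng.normal(size=8)
        assert cosine_similarity(v, -v) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


class TestFeatureEmbedding:
    def test_deterministic_and_fixed_length(self, small_theta):
        backend = FeatureEmbedding()
        img, _, _ = generate_sample(small_theta, seed=4)
        a, b = backend.embed(img), backend.embed(img)
        assert np.array_equal(a, b)
        img2, _, _ = generate_sample(small_theta, seed=5)
        assert len(backend.embed(img2)) == len(a)


class TestObjective:
    def test_identical_reference_scores_one(self, clean_theta):
        img, _, _ = generate_sample(clean_theta, seed=9)
        refs = ReferenceSet([img])
        rec = objective(clean_theta, refs, FeatureEmbedding(), seed=9)
        assert rec.objective == pytest.approx(1.0)

    def test_max_over_references_matches_elementwise_oracle(self, clean_theta):
        backend = FeatureEmbedding()
        refs = ReferenceSet([generate_sample(clean_theta, seed=s)[0]
                             for s in (1, 2, 3)])
        rec = objective(clean_theta, refs, backend, seed=7)
        img, _, _ = generate_sample(clean_theta, seed=7)
        emb = backend.embed(img)
        oracle = [cosine_similarity(emb, backend.embed(r)) for r in refs.images]
        assert rec.per_reference == pytest.approx(oracle)
        assert rec.objective == max(oracle)

    def test_invariant_under_reference_permutation(self, clean_theta):
        backend = FeatureEmbedding()
        imgs = [generate_sample(clean_theta, seed=s)[0] for s in (1, 2, 3)]
        a = objective(clean_theta, ReferenceSet(imgs), backend, seed=7)
        b = objective(clean_theta, ReferenceSet(imgs[::-1]), backend, seed=7)
        assert a.objective == pytest.approx(b.objective)


class TestTune:
    def _flat_theta(self):
        # featureless generator: no filaments, no noise -> constant image
        return default_theta().replace(
            image_h=48, image_w=48, count_mean=0, count_sd=0, seed_len=0,
            noise_gauss_sd=0, photon_scale=0, speckle_sd=0,
            vignette_strength=0, blur_sigma=0, bgfield_amp=0,
            n_spots_mean=0, channel_jitter_sd=0)

    def test_single_trial_returns_the_evaluated_theta(self):
        base = self._flat_theta()
        refs = ReferenceSet([generate_sample(base.replace(background=0.4), 1)[0]])
        config = TunerConfig(n_trials=1, top_k=1, sampler="random", master_seed=0)
        top = tune(SearchSpace({"background": (0.0, 1.0)}), refs,
                   MeanIntensityEmbedding(), config, base=base)
        assert len(top) == 1

    def test_topk_sorted_nonincreasing(self, tmp_path):
        base = self._flat_theta()
        refs = ReferenceSet([generate_sample(base.replace(background=0.4), 1)[0]])
        config = TunerConfig(n_trials=20, top_k=5, sampler="random", master_seed=1)
        top = tune(SearchSpace({"background": (0.0, 1.0)}), refs,
                   MeanIntensityEmbedding(), config,
                   base=base, log_path=tmp_path / "trials.jsonl")
        assert len(top) == 5
        objs = [r.objective for r in top]
        assert objs == sorted(objs, reverse=True)
        assert (tmp_path / "trials.jsonl").read_text().count("\n") == 20

    def test_random_sampler_reproducible_under_seed(self):
        base = self._flat_theta()
        refs = ReferenceSet([generate_sample(base.replace(background=0.4), 1)[0]])
        space = SearchSpace({"background": (0.0, 1.0)})
        config = TunerConfig(n_trials=5, top_k=2, sampler="random", master_seed=3)
        a = tune(space, refs, MeanIntensityEmbedding(), config, base=base)
        b = tune(space, refs, MeanIntensityEmbedding(), config, base=base)
        assert [r.theta for r in a] == [r.theta for r in b]
        assert [r.objective for r in a] == [r.objective for r in b]

    def test_background_level_recovery_within_005(self):
        """200 random-search trials on a 1-parameter toy recover the
        reference background level to 0.05."""
        base = self._flat_theta()
        target = 0.3
        refs = ReferenceSet([generate_sample(base.replace(background=target),
                                             seed=11)[0]])
        config = TunerConfig(n_trials=200, top_k=1, sampler="random",
                             master_seed=2)
        top = tune(SearchSpace({"background": (0.0, 1.0)}), refs,
                   MeanIntensityEmbedding(), config, base=base)
        assert abs(top[0].theta.background - target) < 0.05

    def test_best_so_far_monotone_from_trial_log(self, tmp_path):
        import json
        base = self._flat_theta()
        refs = ReferenceSet([generate_sample(base.replace(background=0.4), 1)[0]])
        config = TunerConfig(n_trials=30, top_k=1, sampler="random", master_seed=4)
        tune(SearchSpace({"background": (0.0, 1.0)}), refs,
             MeanIntensityEmbedding(), config, base=base,
             log_path=tmp_path / "t.jsonl")
        objs = [json.loads(line)["objective"]
                for line in (tmp_path / "t.jsonl").read_text().splitlines()]
        best = np.maximum.accumulate(objs)
        assert np.all(np.diff(best) >= 0)

    def test_empty_space_rejected_before_any_trial(self):
        refs = ReferenceSet([np.zeros((8, 8))])
        with pytest.raises(ValueError):
            tune(SearchSpace({}), refs, MeanIntensityEmbedding(),
                 TunerConfig(n_trials=1, top_k=1))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            TunerConfig(n_trials=0)
        with pytest.raises(ValueError):
            TunerConfig(n_trials=5, top_k=6)


def threshold_segmenter(image, params):
    """Toy: dark pixels below the threshold, split into connected components."""
    gray = image.mean(axis=2) if image.ndim == 3 else image
    fg = gray < params["threshold"]
    labels, _ = ndimage.label(fg)
    return PredictionSet(dialect="labels", shape=gray.shape, labels=labels)


class TestAdaptSegmenter:
    def _tuning_set(self, clean_theta, n=10):
        th = clean_theta.replace(count_mean=1, count_sd=0)
        samples = [generate_sample(th, seed=100 + s) for s in range(n)]
        return [(img, gt) for img, gt, _ in samples if len(gt) > 0]

    def test_toy_threshold_segmenter_reaches_09_mean_skiou(self, clean_theta):
        tuning_set = self._tuning_set(clean_theta)
        space = SearchSpace({"threshold": (0.05, 0.95)}, check_theta_fields=False)
        config = TunerConfig(n_trials=150, top_k=1, sampler="random", master_seed=0)
        result = adapt_segmenter(threshold_segmenter, space, tuning_set,
                                 config, margin=0.3)
        assert result.best_score >= 0.9

    def test_returned_score_reproducible_from_returned_params(self, clean_theta):
        from filasim.tuner import _score_params
        tuning_set = self._tuning_set(clean_theta, n=4)
        space = SearchSpace({"threshold": (0.05, 0.95)}, check_theta_fields=False)
        config = TunerConfig(n_trials=10, top_k=1, sampler="random", master_seed=1)
        result = adapt_segmenter(threshold_segmenter, space, tuning_set, config)
        again = _score_params(threshold_segmenter, result.best_params,
                              tuning_set, margin=0.1)
        assert again == pytest.approx(result.best_score)

    def test_crashing_segmenter_scores_zero_and_run_continues(self, clean_theta):
        tuning_set = self._tuning_set(clean_theta, n=2)

        def flaky(image, params):
            if params["threshold"] < 0.5:
                raise RuntimeError("boom")
            return threshold_segmenter(image, params)

        space = SearchSpace({"threshold": (0.0, 1.0)}, check_theta_fields=False)
        config = TunerConfig(n_trials=10, top_k=1, sampler="random", master_seed=2)
        result = adapt_segmenter(flaky, space, tuning_set, config)
        failed = [t for t in result.trials if t["error"] is not None]
        assert failed and all(t["score"] == 0.0 for t in failed)
        assert len(result.trials) == 10

    def test_empty_tuning_set_rejected(self):
        with pytest.raises(ValueError):
            adapt_segmenter(threshold_segmenter,
                            SearchSpace({"threshold": (0, 1)},
                                        check_theta_fields=False),
                            [], TunerConfig(n_trials=1, top_k=1))

    def test_default_trial_budget_is_1000(self):
        assert TunerConfig().n_trials == 1000
        assert TunerConfig().top_k == 10
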