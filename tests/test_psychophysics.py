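"""2AFC machinery, threshold fits, protocol identities, similarity metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from pitchsim.audio import AudioError
from pitchsim.psychophysics import (
    ConstantEstimator,
    ExperimentA,
    ExperimentB,
    ExperimentC,
    ExperimentD,
    ExperimentE,
    GaussianLogF0Oracle,
    LevelExperiment,
    PsychometricFunction,
    SimilarityScore,
    best_threshold,
    bounded_metric_transform,
    cohens_d,
    fit_threshold,
    human_similarity,
    oracle_threshold_prediction,
    pair_count,
    pairwise_2afc,
    psychometric_function,
    transition_point,
)


class TestPairwise2AFC:
    def test_all_pairs_counted(self, rng):
        """121 stimuli yield 7260 pairwise trials."""
        f0s = np.geomspace(94, 106, 121)
        trials = pairwise_2afc(f0s.copy(), f0s, rng)
        assert len(trials) == 7260

    def test_perfect_estimator_always_correct(self, rng):
        f0s = np.geomspace(100, 120, 30)
        trials = pairwise_2afc(f0s.copy(), f0s, rng)
        assert trials["correct"].all()

    def test_constant_estimator_at_chance(self, rng):
        """A constant prediction leaves only the tie noise: ~50% correct."""
        f0s = np.geomspace(94, 106, 121)
        trials = pairwise_2afc(np.full(121, 100.0), f0s, rng)
        assert trials["correct"].mean() == pytest.approx(0.5, abs=0.02)

    def test_too_few_stimuli(self, rng):
        with pytest.raises(AudioError):
            pairwise_2afc(np.array([1.0]), np.array([100.0]), rng)


class TestThresholdFit:
    def test_recovers_known_cumulative_normal(self):
        """Self-consistency: data generated from a normal CDF yields its own
        criterion point within 2% relative error."""
        mu, s = 0.0, 1.7
        d = np.linspace(0.05, 6.0, 40)
        pf = PsychometricFunction(d, norm.cdf((d - mu) / s),
                                  np.full(40, 500))
        res = fit_threshold(pf)
        expected = mu + s * norm.ppf(0.707)
        assert res.threshold == pytest.approx(expected, rel=0.02)

    def test_chance_everywhere_hits_cap(self):
        d = np.linspace(0.1, 5.0, 20)
        pf = PsychometricFunction(d, np.full(20, 0.5), np.full(20, 100))
        res = fit_threshold(pf)
        assert res.threshold == 100.0 and res.flag == "cap"

    def test_ceiling_everywhere_floors(self):
        d = np.linspace(0.1, 5.0, 20)
        pf = PsychometricFunction(d, np.ones(20), np.full(20, 100))
        res = fit_threshold(pf)
        assert res.flag == "floor" and res.threshold == pytest.approx(0.1)

    @pytest.mark.parametrize("sigma", [0.5, 2.0])
    def test_oracle_closed_form(self, sigma, rng):
        """Monte Carlo 2AFC with a Gaussian log-F0 oracle recovers
        sqrt(2)*sigma*Phi^-1(0.707) within 10%."""
        f0s = np.geomspace(100 * 0.94, 100 * 1.06, 121)
        pf = None
        oracle = GaussianLogF0Oracle(sigma)
        from pitchsim.psychophysics import StimulusSpec

        stims = [StimulusSpec(f, lambda r: None) for f in f0s]
        for _ in range(10):  # 72,600 trials total
            preds = oracle(stims, 100.0, 1.0, rng)
            t = psychometric_function(pairwise_2afc(preds, f0s, rng))
            pf = t if pf is None else pf.pooled_with(t)
        res = fit_threshold(pf)
        assert res.threshold == pytest.approx(
            oracle_threshold_prediction(sigma), rel=0.10)

    def test_monotone_in_oracle_noise(self, rng):
        """Larger oracle noise never gives smaller fitted thresholds."""
        from pitchsim.psychophysics import StimulusSpec

        f0s = np.geomspace(94, 106, 61)
        stims = [StimulusSpec(f, lambda r: None) for f in f0s]
        ths = []
        for sigma in (0.1, 0.5, 2.0):
            oracle = GaussianLogF0Oracle(sigma)
            pf = None
            for _ in range(6):
                preds = oracle(stims, 100.0, 1.0, rng)
                t = psychometric_function(pairwise_2afc(preds, f0s, rng))
                pf = t if pf is None else pf.pooled_with(t)
            ths.append(fit_threshold(pf).threshold)
        assert ths[0] < ths[1] < ths[2]


class TestProtocolIdentities:
    def test_experiment_a_counts(self):
        exp = ExperimentA()
        assert exp.n_conditions == 600
        assert exp.pairs_per_reference == 7260
        assert exp.trials_per_condition == 72600

    def test_experiment_b_counts(self):
        assert ExperimentB().n_stimuli == 2124

    def test_experiment_c_counts(self):
        exp = ExperimentC()
        assert exp.n_cells == 21
        assert exp.n_stimuli == 3 * 7 * 3917

    def test_experiment_d_counts(self):
        exp = ExperimentD()
        assert exp.n_cells == 147
        assert exp.n_stimuli == 26166

    def test_experiment_e_pair_identity(self):
        assert pair_count(684) == 233586
        assert ExperimentE().CARRIERS == (4000.0, 6350.0, 10080.0)

    def test_neurophys_stimulus_count(self):
        from pitchsim.neurophys import tuning_stimuli

        assert tuning_stimuli().n_stimuli == 11520


class TestExperimentRuns:
    def test_experiment_a_oracle_flat_across_harmonics(self, rng):
        """A periphery-blind oracle gives thresholds independent of the
        lowest harmonic number, near the closed-form value."""
        exp = ExperimentA(n_low=(1, 8, 20), n_refs=2, n_stimuli=31)
        df = exp.run(GaussianLogF0Oracle(0.5), rng)
        assert len(df) == 6
        expected = oracle_threshold_prediction(0.5)
        assert np.allclose(df["threshold"], expected, rtol=0.35)
        by_nlow = df.groupby("n_low")["threshold"].mean()
        assert by_nlow.max() / by_nlow.min() < 1.5

    def test_experiment_b_histogram_properties(self, rng):
        """Histogram masses sum to 1; a 2x-reporting estimator puts all its
        mass in the ratio-2 bin."""

        class DoublingOracle:
            def __call__(self, stimuli, centers, octaves, rng):
                return np.array([s.true_f0 * 2.0 for s in stimuli])

        exp = ExperimentB(n_per_cell=12)
        df = exp.run(DoublingOracle(), rng)
        for _, g in df.groupby(["filter", "nominal_f0"]):
            assert g["mass"].sum() == pytest.approx(1.0)
            top = g.loc[g["mass"].idxmax(), "ratio"]
            assert top == pytest.approx(2.0, rel=0.02)

    def test_experiment_c_zero_shift_cells(self, rng):
        """Zero component shift gives ~zero median shift for an oracle."""
        exp = ExperimentC(n_f0s=15)
        df = exp.run(GaussianLogF0Oracle(0.01), rng)
        assert len(df) == 21
        zero = df[df["component_shift"] == 0.0]["median_shift_pct"]
        assert np.all(np.abs(zero) < 0.2)

    def test_experiment_c_spectral_centroid_surrogate(self, rng):
        """An estimator reporting mean component frequency / mean harmonic
        number shows shifts increasing with the component shift."""

        class CentroidOracle:
            def __call__(self, stimuli, centers, octaves, rng):
                out = []
                for s, c in zip(stimuli,
                                np.broadcast_to(centers, (len(stimuli),))):
                    shift = s.meta["shift"]
                    out.append(c * (1 + shift / 100.0 / 5.0))  # ~n_mean = 5
                return np.array(out)

        exp = ExperimentC(n_f0s=7)
        for env in ("low_harmonics",):
            stims_shift = {}
            for shift in (0.0, 8.0, 24.0):
                stims = [type("S", (), {"true_f0": f, "meta": {"shift": shift},
                                        "render": lambda r: None})()
                         for f in exp.f0s]
                preds = CentroidOracle()(stims, exp.f0s, 1.0, rng)
                stims_shift[shift] = np.median(100 * (preds - exp.f0s) / exp.f0s)
            assert stims_shift[0.0] < stims_shift[8.0] < stims_shift[24.0]

    def test_experiment_d_zero_shift_cells(self, rng):
        exp = ExperimentD(n_f0s_per_nominal=5)
        df = exp.run(GaussianLogF0Oracle(0.01), rng)
        assert len(df) == 147
        zero = df[df["component_shift"] == 0.0]["mean_shift_pct"]
        assert np.all(np.abs(zero) < 0.2)

    def test_experiment_e_and_level_run(self, rng):
        exp = ExperimentE(n_stimuli=120)
        df = exp.run(GaussianLogF0Oracle(0.5), rng)
        assert set(df["stimulus_class"]) == {
            "pure", "transposed_4000", "transposed_6350", "transposed_10080"}
        assert len(df) == 20
        assert np.isfinite(df["threshold"]).all()

    def test_level_invariant_oracle_constant_thresholds(self, rng):
        exp = LevelExperiment(n_stimuli=60, levels=(20, 60, 100))
        df = exp.run(GaussianLogF0Oracle(0.5), rng)
        assert len(df) == 3
        # a level-blind oracle gives statistically identical thresholds
        assert df["threshold"].max() / df["threshold"].min() < 1.4


class TestCurveSummaries:
    def test_best_and_transition(self):
        curve = [0.3, 0.4, 0.8, 1.5, 5.0]
        assert best_threshold(curve) == 0.3
        assert transition_point(curve) == 4

    def test_no_transition_sentinel(self):
        assert transition_point([0.2, 0.3, 0.4]) is None

    def test_transition_ignores_later_values(self):
        assert transition_point([0.5, 2.0, 0.1, 9.0]) == 2


class TestSimilarity:
    def make_model_a(self):
        rows = []
        for phase in ("sine", "random"):
            for n_low in range(1, 31):
                rows.append({"phase": phase, "n_low": n_low,
                             "threshold": 0.4 if n_low <= 7 else 5.0})
        return pd.DataFrame(rows)

    def load_human(self):
        from importlib import resources

        with resources.files("pitchsim.data").joinpath(
                "human_reference_synthetic.csv").open() as f:
            return pd.read_csv(f, comment="#")

    def test_experiment_a_vector_length_and_bounds(self):
        model = self.make_model_a()
        human = self.load_human()
        h = human[human["experiment"] == "A"]
        score = human_similarity(model, h, "A")
        assert score.n == 60
        assert -1.0 <= score.r <= 1.0
        assert score.transform == "log"

    def test_identical_vectors_r1(self):
        model = self.make_model_a()
        human = model.rename(columns={"phase": "condition",
                                      "threshold": "value"})
        assert human_similarity(model, human, "A").r == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        model = self.make_model_a()
        human = model.rename(columns={"phase": "condition",
                                      "threshold": "value"})
        human["value"] = 1.0 / human["value"]  # inverted in log space
        assert human_similarity(model, human, "A").r == pytest.approx(-1.0)

    def test_symmetry_and_affine_invariance(self):
        model = self.make_model_a()
        human = model.rename(columns={"phase": "condition",
                                      "threshold": "value"})
        base = human_similarity(model, human, "A").r
        human2 = human.copy()
        human2["value"] = human2["value"] ** 2.0 * 7.0  # affine in log space
        assert human_similarity(model, human2, "A").r == pytest.approx(base)

    def test_too_few_points_rejected(self):
        with pytest.raises(AudioError):
            SimilarityScore(0.5, 2, "none")


class TestStatsHelpers:
    def test_cohens_d_known_value(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 2.0
        assert cohens_d(b, a) == pytest.approx(2.0 / a.std(ddof=1))

    def test_bounded_transform_monotone_and_centered(self):
        rs = np.array([-0.9, 0.0, 0.9])
        z = bounded_metric_transform(rs)
        assert z[1] == pytest.approx(0.0)
        assert np.all(np.diff(z) > 0)
        zf = bounded_metric_transform(rs, "fisher")
        assert np.all(np.diff(zf) > 0)
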