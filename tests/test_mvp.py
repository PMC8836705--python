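import numpy as np
import pandas as pd
import pytest

from episig import (MVPModel, SimConfig, TrainConfig, discover_signature,
                    score_samples, simulate_cohort, train_mvp,
                    train_specificity_model)


@pytest.fixture(scope="module")
def trained(cc_setup_module):
    setup = cc_setup_module
    sig, _ = discover_signature(setup["beta"], setup["labels"])
    model = train_mvp(setup["beta"].loc[sig.probe_ids], setup["labels"],
                      TrainConfig(seed=0))
    return sig, model


@pytest.fixture(scope="module")
def cc_setup_module(request):
    # session fixtures cannot be requested by module fixtures' params; reuse
    # the session-scoped one through the request
    return request.getfixturevalue("cc_setup")


class TestTrainMVP:
    def test_separable_training_is_perfect(self, cc_setup_module, trained):
        sig, model = trained
        assert model.cv_accuracy == 1.0
        scores = score_samples(model, cc_setup_module["beta"])
        lab = cc_setup_module["labels"]
        assert (scores.loc[lab == "case", "mvp_score"] > 0.5).all()
        assert (scores.loc[lab == "control", "mvp_score"] < 0.5).all()

    def test_single_class_rejected(self, cc_setup_module):
        beta = cc_setup_module["beta"].iloc[:50]
        labels = pd.Series("case", index=beta.columns)
        with pytest.raises(ValueError):
            train_mvp(beta, labels)

    def test_shuffled_labels_score_near_chance(self, cc_setup_module):
        beta = cc_setup_module["beta"].iloc[:200]
        lab = cc_setup_module["labels"]
        rng = np.random.default_rng(3)
        accs = []
        for _ in range(3):
            shuffled = pd.Series(rng.permutation(lab.to_numpy()),
                                 index=lab.index)
            model = train_mvp(beta, shuffled, TrainConfig(seed=1))
            accs.append(model.cv_accuracy)
        assert 0.2 < np.mean(accs) < 0.8

    def test_ties_prefer_smallest_cost(self, rng):
        # hugely separated blobs are perfect at every grid cost, so the
        # smallest (most regularized) cost must be chosen
        x = np.vstack([rng.normal(0, 0.1, (10, 5)), rng.normal(10, 0.1, (10, 5))])
        beta = pd.DataFrame(np.clip(x.T / 20 + 0.5, 0, 1),
                            columns=[f"s{i}" for i in range(20)])
        labels = pd.Series(["case"] * 10 + ["control"] * 10, index=beta.columns)
        model = train_mvp(beta, labels, TrainConfig(seed=0))
        assert model.cv_accuracy == 1.0
        assert model.cost == 0.001


class TestScoreSamples:
    def test_scores_bounded(self, cc_setup_module, trained, rng):
        _, model = trained
        random_profiles = pd.DataFrame(
            rng.random((len(model.probe_ids), 30)),
            index=model.probe_ids,
            columns=[f"r{i}" for i in range(30)],
        )
        scores = score_samples(model, random_profiles)
        assert (scores["mvp_score"] >= 0).all() and (scores["mvp_score"] <= 1).all()

    def test_score_monotone_in_decision_value(self, cc_setup_module, trained):
        _, model = trained
        scores = score_samples(model, cc_setup_module["beta_full"])
        ordered = scores.sort_values("decision_value")
        assert ordered["mvp_score"].is_monotonic_increasing

    def test_boundary_score_is_sigmoid_identity(self, trained):
        _, model = trained
        # decision value 0 maps to 1/(1+e^B) by construction
        x = pd.DataFrame(np.zeros((len(model.probe_ids), 1)),
                         index=model.probe_ids, columns=["z"])
        w = model.weights
        # construct a sample exactly on the hyperplane: x = -b*w/(w.w)
        x["z"] = -model.bias * w / (w @ w)
        s = score_samples(model, x)
        assert s.loc["z", "decision_value"] == pytest.approx(0.0, abs=1e-9)
        expected = 1.0 / (1.0 + np.exp(model.sigmoid_b))
        assert s.loc["z", "mvp_score"] == pytest.approx(expected)

    def test_duplicate_sample_same_score(self, cc_setup_module, trained):
        _, model = trained
        case0 = cc_setup_module["case_ids"][0]
        beta = cc_setup_module["beta"]
        dup = beta[[case0]].rename(columns={case0: "copy"})
        both = pd.concat([beta[[case0]], dup], axis=1)
        s = score_samples(model, both)
        assert s.loc[case0, "mvp_score"] == s.loc["copy", "mvp_score"]

    def test_serialization_roundtrip_reproduces_scores(self, cc_setup_module,
                                                       trained, tmp_path):
        _, model = trained
        model.save(tmp_path / "model.json")
        back = MVPModel.load(tmp_path / "model.json")
        a = score_samples(model, cc_setup_module["beta"])["mvp_score"]
        b = score_samples(back, cc_setup_module["beta"])["mvp_score"]
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_heldout_case_outranks_heldout_control(self, cc_setup_module):
        """Held-out cases score above held-out controls in >= 99% of pairs."""
        setup = cc_setup_module
        held_cases = setup["case_ids"][:3]
        held_ctrls = setup["control_ids"][:6]
        train_cols = [c for c in setup["labels"].index
                      if c not in held_cases + held_ctrls]
        lab = setup["labels"][train_cols]
        sig, _ = discover_signature(setup["beta"][train_cols], lab)
        model = train_mvp(setup["beta"].loc[sig.probe_ids, train_cols], lab)
        s = score_samples(model, setup["beta_full"].loc[sig.probe_ids])
        pairs = [
            (s.loc[c, "mvp_score"], s.loc[k, "mvp_score"])
            for c in held_cases for k in held_ctrls
        ]
        frac = np.mean([a > b for a, b in pairs])
        assert frac >= 0.99


@pytest.fixture(scope="module")
def confounded():
    """Cohort with an extra disorder sharing 30% of the spiked probes."""
    cfg = SimConfig(n_probes=3000, n_cases=12, n_control_pool=60,
                    n_other_cohorts=1, n_samples_per_other_cohort=12,
                    n_spiked_dmps=300, other_overlap=0.3, seed=19)
    c = simulate_cohort(cfg)
    cases = sorted(c.samples.index[c.samples["group"] == "case"])
    ctrls = sorted(c.samples.index[c.samples["group"] == "control_pool"])[:24]
    others = sorted(c.samples.index[
        c.samples["group"].str.startswith("other_cohort:")])
    labels = pd.Series(["case"] * len(cases) + ["control"] * len(ctrls),
                       index=cases + ctrls)
    sig, _ = discover_signature(c.beta[cases + ctrls], labels)
    return c, sig, labels, others


class TestSpecificityModel:
    def test_zero_other_cohorts_rejected(self, confounded):
        c, sig, labels, _ = confounded
        with pytest.raises(ValueError):
            train_specificity_model(c.beta, labels, {}, sig)

    def test_overlap_cohort_scores_drop_under_specificity_training(self, confounded):
        c, sig, labels, others = confounded
        naive = train_mvp(c.beta.loc[sig.probe_ids, labels.index], labels)
        naive_scores = score_samples(naive, c.beta.loc[sig.probe_ids, others])
        spec_model, spec_scores = train_specificity_model(
            c.beta, labels, {"other0": others}, sig)
        spec_other = spec_scores.loc[others, "mvp_score"]
        # shared probes make the confounder score high on the naive model;
        # adding it to the negative class pushes it down
        assert spec_other.mean() < naive_scores["mvp_score"].mean()
        assert (spec_other < 0.5).all()

    def test_cases_stay_high_under_specificity_training(self, confounded):
        c, sig, labels, others = confounded
        _, scores = train_specificity_model(c.beta, labels, {"other0": others},
                                            sig)
        assert (scores.loc[labels[labels == "case"].index, "mvp_score"] > 0.5).all()
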