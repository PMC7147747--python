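"""Policy comparisons, operating-point sweeps, curation experiments."""

import math

import pytest

from drscreen.grading import THREE_CLASS, TWO_CLASS
from drscreen.metrics import compute_metrics, confusion
from drscreen.policies import (
    ArgmaxPolicy,
    CascadingPolicy,
    MarginMaxPolicy,
    ProbRecord,
    apply_policy,
)
from drscreen.quality import QualityScore
from drscreen.synthetic import (
    SCREENING_PREVALENCE_3,
    ProbGenConfig,
    gen_prob_records,
    screening_preset,
)
from drscreen.workbench import (
    SweepSpec,
    policy_label,
    run_comparison,
    run_curation_experiment,
    sweep,
)

H, N, R = THREE_CLASS.classes


def perfect_records(n=60):
    recs = []
    for i in range(n):
        cls = THREE_CLASS.classes[i % 3]
        probs = tuple(0.98 if c == cls else 0.01 for c in THREE_CLASS.classes)
        recs.append(ProbRecord(i, probs, THREE_CLASS, true_label=cls))
    return recs


class TestComparison:
    def test_perfect_classifier_all_columns_identical(self):
        recs = perfect_records()
        rep = run_comparison(
            recs,
            [MarginMaxPolicy.boosting(H, 0.4, THREE_CLASS),
             CascadingPolicy.uniform(0.5, THREE_CLASS)],
            THREE_CLASS,
        )
        for col in rep.columns.values():
            assert col.accuracy == 1.0
            for c in THREE_CLASS.classes:
                assert col.per_class[c]["sensitivity"] == 1.0

    def test_boosting_healthy_raises_healthy_sensitivity(self, screening_records):
        rep = run_comparison(
            screening_records,
            [MarginMaxPolicy.boosting(H, 0.4, THREE_CLASS)],
            THREE_CLASS,
        )
        boosted = rep["Margin Max (0.4) preferring Healthy"]
        assert (
            boosted.per_class[H]["sensitivity"]
            >= rep["Original"].per_class[H]["sensitivity"]
        )

    def test_single_policy_gives_two_columns(self, screening_records):
        rep = run_comparison(
            screening_records[:100],
            [CascadingPolicy.uniform(0.3, THREE_CLASS)],
            THREE_CLASS,
        )
        assert len(rep.columns) == 2
        assert "Original" in rep.columns
        assert rep.provenance["n_records"] == 100

    def test_cells_equal_metrics_module_output(self, screening_records):
        pol = CascadingPolicy.uniform(0.3, THREE_CLASS)
        rep = run_comparison(screening_records, [pol], THREE_CLASS)
        preds = [p for _, p in apply_policy(screening_records, pol)]
        truth = [r.true_label for r in screening_records]
        direct = compute_metrics(confusion(truth, preds, THREE_CLASS))
        col = rep[policy_label(pol)]
        assert col.accuracy == direct.accuracy
        assert col.per_class == direct.per_class

    def test_two_class_healthy_boost_raises_diseased_specificity(self):
        # the binary mirror: uplifting Healthy sensitivity is identically
        # an uplift of Diseased specificity
        conc = {"Healthy": (6.0, 2.0), "Diseased": (2.5, 4.0)}
        cfg = ProbGenConfig(TWO_CLASS, 4000, {"Healthy": 0.74, "Diseased": 0.26},
                            conc, seed=11)
        recs = gen_prob_records(cfg)
        rep = run_comparison(
            recs, [MarginMaxPolicy.boosting("Healthy", 0.4, TWO_CLASS)], TWO_CLASS
        )
        orig = rep["Original"]
        boosted = rep["Margin Max (0.4) preferring Healthy"]
        assert (boosted.per_class["Healthy"]["sensitivity"]
                > orig.per_class["Healthy"]["sensitivity"])
        assert (boosted.per_class["Diseased"]["specificity"]
                > orig.per_class["Diseased"]["specificity"])
        assert boosted.per_class["Diseased"]["specificity"] == pytest.approx(
            boosted.per_class["Healthy"]["sensitivity"]
        )

    def test_requires_a_policy(self, screening_records):
        with pytest.raises(ValueError, match="at least one"):
            run_comparison(screening_records[:10], [], THREE_CLASS)


class TestSweep:
    def test_trivial_objective_met(self, screening_records):
        spec = SweepSpec("marginmax", (0.0, 0.2), objective_class=H, target=0.0)
        res = sweep(screening_records, spec, THREE_CLASS)
        assert res.objective_met

    def test_sensitivities_nondecreasing_along_margin_grid(self, screening_records):
        grid = (0.0, 0.2, 0.4)
        spec = SweepSpec("marginmax", grid, objective_class=H, target=0.9)
        res = sweep(screening_records, spec, THREE_CLASS)
        sens = [
            res.report[policy_label(spec.build_policy(g, THREE_CLASS))]
            .per_class[H]["sensitivity"]
            for g in grid
        ]
        assert sens == sorted(sens)

    def test_unreachable_objective_flagged(self, screening_records):
        spec = SweepSpec("marginmax", (0.0, 0.2), objective_class=H, target=1.01)
        res = sweep(screening_records, spec, THREE_CLASS)
        assert not res.objective_met

    def test_ties_prefer_smallest_parameter(self):
        # perfect classifier: every margin meets the objective with equal
        # specificity, so the least aggressive boost wins
        recs = perfect_records()
        spec = SweepSpec("marginmax", (0.0, 0.2, 0.4), objective_class=H,
                         target=0.99)
        res = sweep(recs, spec, THREE_CLASS)
        assert res.objective_met and res.chosen == 0.0

    def test_cascade_sweep_builds_uniform_thresholds(self, screening_records):
        spec = SweepSpec("cascade", (0.2, 0.3, 0.5), objective_class=R,
                         target=0.6)
        res = sweep(screening_records, spec, THREE_CLASS)
        assert res.chosen in spec.grid

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            SweepSpec("marginmax", ())


def coupled_quality_records(seed=0, n_good=3000, n_bad=1000):
    """Good-quality ids get a confident classifier, bad ids a noisy one."""
    good = gen_prob_records(screening_preset(n_good, seed=seed))
    flat = {c: (1.2, 1.1, 1.0) for c in THREE_CLASS.classes}
    bad_cfg = ProbGenConfig(THREE_CLASS, n_bad, SCREENING_PREVALENCE_3, flat,
                            seed=seed + 1)
    bad = gen_prob_records(bad_cfg)
    records, scores = [], []
    for i, r in enumerate(good):
        rid = f"g{i}"
        records.append(ProbRecord(rid, r.probs, THREE_CLASS, r.true_label))
        scores.append(QualityScore(rid, 0.9, "adequate"))
    for i, r in enumerate(bad):
        rid = f"b{i}"
        records.append(ProbRecord(rid, r.probs, THREE_CLASS, r.true_label))
        scores.append(QualityScore(rid, 0.2, "inadequate"))
    return records, scores


class TestCurationExperiment:
    policies = [MarginMaxPolicy.boosting(H, 0.4, THREE_CLASS)]

    def test_threshold_zero_reports_identical(self):
        records, scores = coupled_quality_records(seed=3, n_good=400, n_bad=100)
        exp = run_curation_experiment(records, scores, 0.0, self.policies,
                                      THREE_CLASS)
        assert exp.curation.rejection_rate == 0.0
        assert exp.uncurated.to_frame().equals(exp.curated.to_frame())

    def test_threshold_one_flags_empty_curated_set(self):
        records, scores = coupled_quality_records(seed=4, n_good=50, n_bad=20)
        exp = run_curation_experiment(records, scores, 1.0, self.policies,
                                      THREE_CLASS)
        assert exp.curated_empty
        assert exp.curation.rejection_rate == 1.0

    def test_curation_improves_accuracy_on_coupled_set(self):
        records, scores = coupled_quality_records(seed=5)
        exp = run_curation_experiment(records, scores, 0.5, self.policies,
                                      THREE_CLASS)
        assert exp.curation.rejection_rate == pytest.approx(1000 / 4000)
        assert (exp.curated["Original"].accuracy
                >= exp.uncurated["Original"].accuracy)

    def test_report_text_has_provenance_header(self, screening_records):
        rep = run_comparison(screening_records[:200], self.policies, THREE_CLASS)
        text = rep.to_text()
        assert "config_hash" in text
        assert "accuracy" in text.splitlines()[1]
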