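"""Normalization, enrichment ratios, truth sets, and the ROC cutoff —
including a brute-force oracle for the Youden-J selection."""

import numpy as np
import pandas as pd
import pytest

from secretomap import ValidationError
from secretomap.io_tables import AnnotationCatalog
from secretomap.roc_filter import (RocCurve, TruthSets, apply_filter, build_roc,
                                   build_truth_sets, compute_enrichment_ratios,
                                   normalize_channels)

from conftest import FOUR_CHANNEL, make_experiment


def brute_force_cutoff(tp_ratios, fp_ratios):
    """Independent oracle: enumerate TPR-FPR over every distinct ratio,
    keep the maximizer, ties toward the smaller cutoff."""
    tp, fp = np.asarray(tp_ratios), np.asarray(fp_ratios)
    best = None
    for t in np.unique(np.concatenate([tp, fp])):
        j = (tp >= t).mean() - (fp >= t).mean()
        if best is None or j > best[1] or (j == best[1] and t < best[0]):
            best = (t, j)
    return best


def catalog_from(cc: dict[str, set[str]], signal_peptide=()) -> AnnotationCatalog:
    rows = {pid: {"cc_terms": frozenset(terms), "signal_peptide": pid in signal_peptide,
                  "ups_predicted": False, "transmembrane": False,
                  "tissue_enriched": None, "concentration_pmol_ml": np.nan}
            for pid, terms in cc.items()}
    t = pd.DataFrame.from_dict(rows, orient="index",
                               columns=list(AnnotationCatalog.COLUMNS))
    t.index.name = "protein"
    return AnnotationCatalog(t)


class TestNormalization:
    def test_median_center_fixed_point(self):
        q = make_experiment({"A": [4, 4, 4, 4], "B": [16, 16, 16, 16]}, FOUR_CHANNEL)
        out = normalize_channels(q, "median_center")
        pd.testing.assert_frame_equal(out.intensities, q.intensities)

    def test_total_sum_equalizes_doubled_channel(self):
        q = make_experiment({"A": [10, 20, 10, 10], "B": [30, 60, 30, 30]}, FOUR_CHANNEL)
        out = normalize_channels(q, "total_sum")
        np.testing.assert_allclose(out.intensities.sum(axis=0), 50.0)

    def test_missing_cells_stay_missing(self):
        q = make_experiment({"A": [np.nan, 4, 4, 4], "B": [16, 16, 16, 16]}, FOUR_CHANNEL)
        for method in ("median_center", "total_sum", "none"):
            out = normalize_channels(q, method)
            assert np.isnan(out.intensities.at["A", "c1"])

    def test_all_missing_channel_names_the_channel(self):
        q = make_experiment({"A": [np.nan, 4, 4, 4]}, FOUR_CHANNEL)
        with pytest.raises(ValidationError, match="c1"):
            normalize_channels(q, "median_center")


class TestEnrichmentRatios:
    def test_closed_form_ratio(self, simple_experiment):
        ratios = compute_enrichment_ratios(simple_experiment)
        assert ratios["A"] == pytest.approx(3.0)   # log2(800/100)
        assert ratios["B"] == pytest.approx(0.0)

    def test_equal_genotypes_give_zero_everywhere(self):
        q = make_experiment({"A": [7, 7, 7, 7], "B": [3, 3, 3, 3]}, FOUR_CHANNEL)
        np.testing.assert_allclose(compute_enrichment_ratios(q), 0.0)

    def test_underquantified_protein_dropped(self):
        q = make_experiment({"A": [800, 800, np.nan, np.nan], "B": [5, 5, 5, 5]},
                            FOUR_CHANNEL)
        ratios = compute_enrichment_ratios(q, min_frac_quantified=0.5)
        assert "A" not in ratios.index and "B" in ratios.index

    def test_zero_background_floored_not_infinite(self):
        q = make_experiment({"A": [800, 800, 0, 0], "B": [5, 5, 5, 5]}, FOUR_CHANNEL)
        ratios = compute_enrichment_ratios(q)
        assert np.isfinite(ratios["A"])
        # floor is half the smallest positive intensity (5/2)
        assert ratios["A"] == pytest.approx(np.log2(800 / 2.5))


class TestTruthSets:
    def test_construction_rules(self):
        cat = catalog_from({"er": {"endoplasmic reticulum"}, "nuc": {"nucleus"},
                            "dual": {"endoplasmic reticulum", "nucleus"},
                            "sp": set(), "mixed": {"nucleus", "ribosome"}},
                           signal_peptide=("sp",))
        ts = build_truth_sets(cat, ["er", "nuc", "dual", "sp", "mixed", "unknown"])
        assert ts.true_positives == {"er", "dual", "sp"}   # secretory precedence
        assert ts.false_positives == {"nuc"}               # 'mixed' not contained
        assert "unknown" not in ts.true_positives | ts.false_positives

    def test_empty_side_instructs_user(self):
        cat = catalog_from({"er": {"endoplasmic reticulum"}})
        with pytest.raises(ValidationError, match="annotation"):
            build_truth_sets(cat, ["er"])

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            TruthSets(frozenset("A"), frozenset("A"), "rule")


class TestRocCurve:
    TRUTH = TruthSets(frozenset({"t1", "t2", "t3"}), frozenset({"f1", "f2"}), "test")

    def test_worked_example_enumerated_by_hand(self):
        # TP ratios {4,2,1}, FP {3,0.5}: J over the 5 cutoffs peaks at 1
        ratios = {"t1": 4.0, "t2": 2.0, "t3": 1.0, "f1": 3.0, "f2": 0.5}
        roc = build_roc(ratios, self.TRUTH)
        assert roc.selected_cutoff == pytest.approx(1.0)
        assert roc.selected_j == pytest.approx(0.5)

    def test_perfect_separation(self):
        ratios = {"t1": 5.0, "t2": 4.0, "t3": 3.0, "f1": 1.0, "f2": 0.0}
        roc = build_roc(ratios, self.TRUTH)
        assert roc.selected_j == pytest.approx(1.0)
        assert roc.auc == pytest.approx(1.0)

    def test_exchangeable_classes_give_zero_j(self):
        ratios = {"t1": 1.0, "t2": 2.0, "f1": 1.0, "f2": 2.0}
        truth = TruthSets(frozenset({"t1", "t2"}), frozenset({"f1", "f2"}), "test")
        assert build_roc(ratios, truth).selected_j == pytest.approx(0.0)

    def test_degenerate_identical_ratios(self):
        ratios = {"t1": 1.0, "f1": 1.0}
        truth = TruthSets(frozenset({"t1"}), frozenset({"f1"}), "test")
        with pytest.raises(ValidationError, match="degenerate"):
            build_roc(ratios, truth)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n_tp = rng.integers(2, 26)
            n_fp = rng.integers(2, 26)
            tp = np.round(rng.normal(2, 1.5, n_tp), 2)
            fp = np.round(rng.normal(0, 1.5, n_fp), 2)
            ratios = {f"t{i}": v for i, v in enumerate(tp)}
            ratios.update({f"f{i}": v for i, v in enumerate(fp)})
            truth = TruthSets(frozenset(k for k in ratios if k.startswith("t")),
                              frozenset(k for k in ratios if k.startswith("f")), "r")
            roc = build_roc(ratios, truth)
            cut, j = brute_force_cutoff(tp, fp)
            assert roc.selected_cutoff == pytest.approx(cut)
            assert roc.selected_j == pytest.approx(j)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        tp = rng.normal(2, 1, 30)
        fp = rng.normal(0, 1, 20)
        ratios = {f"t{i}": v for i, v in enumerate(tp)}
        ratios.update({f"f{i}": v for i, v in enumerate(fp)})
        truth = TruthSets(frozenset(k for k in ratios if k.startswith("t")),
                          frozenset(k for k in ratios if k.startswith("f")), "r")
        roc = build_roc(ratios, truth)
        y = np.concatenate([np.ones(30), np.zeros(20)])
        scores = np.concatenate([tp, fp])
        assert roc.auc == pytest.approx(roc_auc_score(y, scores))

    def test_shift_invariance(self):
        ratios = {"t1": 4.0, "t2": 2.0, "t3": 1.0, "f1": 3.0, "f2": 0.5}
        r1 = build_roc(ratios, self.TRUTH)
        shifted = {k: v + 2.5 for k, v in ratios.items()}
        r2 = build_roc(shifted, self.TRUTH)
        assert r2.auc == pytest.approx(r1.auc)
        assert r2.selected_j == pytest.approx(r1.selected_j)
        assert r2.selected_cutoff == pytest.approx(r1.selected_cutoff + 2.5)

    def test_fixed_fpr_operating_point(self):
        ratios = {"t1": 4.0, "t2": 2.0, "t3": 1.0, "f1": 3.0, "f2": 0.5}
        roc = build_roc(ratios, self.TRUTH, fixed_fpr=0.0)
        assert roc.selected_cutoff == pytest.approx(4.0)
        assert roc.fpr[np.where(roc.cutoffs == roc.selected_cutoff)][0] == 0.0


class TestApplyFilter:
    ROC = RocCurve(np.array([1.0]), np.array([1.0]), np.array([0.0]), 1.0,
                   selected_cutoff=1.0, selected_j=1.0)

    def test_boundary_is_inclusive(self):
        res = apply_filter({"A": 1.2, "B": 1.0, "C": 0.9}, self.ROC)
        assert res.passing == {"A", "B"}
        assert res.n_identified == 3 and res.n_passing == 2

    def test_empty_mapping(self):
        res = apply_filter({}, self.ROC)
        assert res.passing == frozenset() and res.n_identified == 0

    def test_raising_cutoff_never_enlarges_passing_set(self, rng):
        ratios = dict(zip([f"p{i}" for i in range(50)], rng.normal(1, 2, 50)))
        previous = None
        for cutoff in np.linspace(-3, 5, 9):
            roc = RocCurve(np.array([cutoff]), np.array([1.0]), np.array([0.0]),
                           1.0, selected_cutoff=float(cutoff), selected_j=1.0)
            passing = apply_filter(ratios, roc).passing
            if previous is not None:
                assert passing <= previous
            previous = passing
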