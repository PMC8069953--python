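"""Per-study standardized effects and DerSimonian--Laird combination."""

import numpy as np
import pandas as pd
import pytest

from dmdnet.meta import (
    ExpressionStudy,
    RandomEffectsMeta,
    combine_random_effects,
    compute_study_effects,
)
from dmdnet.synthetic import generate_expression_studies


def make_study(data: dict[str, list[float]], groups: list[str],
               study_id: str = "s1") -> ExpressionStudy:
    samples = [f"x{i}" for i in range(len(groups))]
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    return ExpressionStudy(study_id=study_id, matrix=matrix,
                           groups=pd.Series(groups, index=samples))


class TestStudyEffects:
    def test_hand_calculation(self):
        # control {1,2,3}, case {3,4,5}: pooled SD 1, d=2, J=0.8, g=1.6, v=0.88
        study = make_study({"g1": [1, 2, 3, 3, 4, 5]},
                           ["control"] * 3 + ["case"] * 3)
        eff = compute_study_effects(study)
        assert eff.loc["g1", "d"] == pytest.approx(2.0)
        assert eff.loc["g1", "g"] == pytest.approx(1.6)
        assert eff.loc["g1", "v"] == pytest.approx(6 / 9 + 1.6**2 / 12)

    def test_equal_means_give_zero_effect(self):
        study = make_study({"g1": [1, 2, 3, 1, 2, 3]},
                           ["control"] * 3 + ["case"] * 3)
        eff = compute_study_effects(study)
        assert eff.loc["g1", "d"] == 0.0
        assert eff.loc["g1", "g"] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=12).tolist()
        base = make_study({"g1": values}, ["control"] * 6 + ["case"] * 6)
        scaled = make_study({"g1": [7.3 * v for v in values]},
                            ["control"] * 6 + ["case"] * 6)
        assert compute_study_effects(base).loc["g1", "g"] == pytest.approx(
            compute_study_effects(scaled).loc["g1", "g"]
        )

    def test_zero_pooled_sd_excluded(self):
        study = make_study(
            {"flat": [1, 1, 1, 1, 1, 1], "ok": [1, 2, 3, 4, 5, 6]},
            ["control"] * 3 + ["case"] * 3,
        )
        eff = compute_study_effects(study)
        assert "flat" not in eff.index and "ok" in eff.index

    def test_duplicate_probes_collapse_to_largest_abs_d(self):
        samples = [f"x{i}" for i in range(6)]
        matrix = pd.DataFrame(
            [[1, 2, 3, 3, 4, 5], [1, 2, 3, 1.1, 2.1, 3.1]],
            index=["g1", "g1"], columns=samples,
        )
        study = ExpressionStudy(
            study_id="s", matrix=matrix,
            groups=pd.Series(["control"] * 3 + ["case"] * 3, index=samples),
        )
        eff = compute_study_effects(study)
        assert len(eff) == 1
        assert eff.loc["g1", "d"] == pytest.approx(2.0)

    def test_too_few_samples_per_group_rejected(self):
        with pytest.raises(ValueError, match="group 'case'"):
            make_study({"g1": [1, 2, 3, 4]}, ["control"] * 3 + ["case"])


class TestCombine:
    def test_single_study_identity(self):
        eff = pd.DataFrame({"g": [1.6], "v": [0.88]}, index=["g1"])
        table = combine_random_effects([eff])
        row = table.loc["g1"]
        assert row["combined_es"] == pytest.approx(1.6)
        assert row["tau2"] == 0.0
        assert row["z"] == pytest.approx(1.6 / np.sqrt(0.88))
        assert row["n_studies"] == 1

    def test_two_identical_studies(self):
        eff = pd.DataFrame({"g": [1.0], "v": [0.5]}, index=["g1"])
        table = combine_random_effects([eff, eff.copy()])
        row = table.loc["g1"]
        assert row["tau2"] == 0.0  # Q = 0
        assert row["combined_es"] == pytest.approx(1.0)
        assert row["z"] == pytest.approx(1.0 / np.sqrt(0.25))  # pooled variance 1/4

    def test_gene_on_subset_of_platforms(self):
        e1 = pd.DataFrame({"g": [1.0, 0.5], "v": [0.5, 0.5]}, index=["g1", "g2"])
        e2 = pd.DataFrame({"g": [1.0], "v": [0.5]}, index=["g1"])
        table = combine_random_effects([e1, e2])
        assert table.loc["g1", "n_studies"] == 2
        assert table.loc["g2", "n_studies"] == 1
        assert table.loc["g2", "combined_es"] == pytest.approx(0.5)

    def test_label_swap_negates_effect_preserves_p(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=16).tolist()
        a = make_study({"g1": values}, ["control"] * 8 + ["case"] * 8)
        b = make_study({"g1": values}, ["case"] * 8 + ["control"] * 8)
        ta = combine_random_effects([compute_study_effects(a)])
        tb = combine_random_effects([compute_study_effects(b)])
        assert ta.loc["g1", "combined_es"] == pytest.approx(-tb.loc["g1", "combined_es"])
        assert ta.loc["g1", "p"] == pytest.approx(tb.loc["g1", "p"])


class TestModelResults:
    def test_fit_and_deg_thresholds_are_strict(self):
        studies, _ = generate_expression_studies(
            n_studies=3, n_genes=300, deg_fraction=0.1, seed=5
        )
        results = RandomEffectsMeta(studies).fit()
        table = results.table.copy()
        # strictness: plant rows at the exact thresholds
        table.loc["edge1"] = {"combined_es": 2.0, "tau2": 0, "z": 5, "p": 1e-5,
                              "fdr": 0.04, "n_studies": 3, "direction": "up"}
        table.loc["edge2"] = {"combined_es": 2.5, "tau2": 0, "z": 5, "p": 1e-5,
                              "fdr": 0.05, "n_studies": 3, "direction": "up"}
        table.loc["edge3"] = {"combined_es": -2.5, "tau2": 0, "z": -5, "p": 1e-5,
                              "fdr": 0.04, "n_studies": 3, "direction": "down"}
        results.table = table
        degs = results.call_degs(fdr_max=0.05, es_min=2.0)
        assert "edge1" not in degs.genes  # |ES| not strictly > 2
        assert "edge2" not in degs.genes  # FDR not strictly < 0.05
        assert "edge3" in degs.down

    def test_summary_mentions_studies_and_degs(self):
        studies, _ = generate_expression_studies(n_studies=2, n_genes=100, seed=2)
        text = RandomEffectsMeta(studies).fit().summary()
        assert "studies:  2" in text and "DEGs:" in text

    def test_null_type_one_error_is_valid(self):
        """Under the complete null the combined test controls its level.

        The DL Wald z-test is conservative at few studies, so the rejection
        rate must not exceed alpha beyond Monte-Carlo error.
        """
        studies, _ = generate_expression_studies(
            n_studies=3, n_genes=4000, deg_fraction=0.0, seed=11
        )
        table = RandomEffectsMeta(studies).fit().table
        rate = float((table["p"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(table))
        assert rate <= 0.05 + 3 * se

    def test_planted_recovery_single_seed(self):
        studies, truth = generate_expression_studies(
            n_studies=3, n_genes=1000, deg_fraction=0.05, effect_magnitude=3.0, seed=3
        )
        degs = RandomEffectsMeta(studies).fit().call_degs()
        planted = truth.deg_genes_up | truth.deg_genes_down
        recall = len(degs.genes & planted) / len(planted)
        fdp = len(degs.genes - planted) / max(1, len(degs.genes))
        assert recall >= 0.9
        assert fdp <= 0.10
        assert degs.up <= truth.deg_genes_up and degs.down <= truth.deg_genes_down

    def test_file_round_trip(self, tmp_path):
        from dmdnet.io import write_expression

        studies, _ = generate_expression_studies(n_studies=1, n_genes=50, seed=9)
        study = studies[0]
        write_expression(tmp_path / "e.tsv", tmp_path / "d.tsv", study.matrix, study.groups)
        loaded = ExpressionStudy.from_files("s1", tmp_path / "e.tsv", tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(loaded.matrix, study.matrix)
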