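"""The 9-cell bias classification, gene rollup and landscape tabulation."""

import numpy as np
import pandas as pd
import pytest
from conftest import SEED

from exonde.landscape import (
    BETWEEN_SEX_LABELS,
    BIAS_LABELS,
    WITHIN_SEX_LABELS,
    GeneCategoryAssignment,
    classify_between_sex,
    classify_within_sex,
    percent,
    rollup_gene,
    tabulate_landscape,
)


class TestBetweenSexClassification:
    def test_label_map_is_a_bijection_over_nine_cells(self):
        assert len(BETWEEN_SEX_LABELS) == 9
        assert len(set(BETWEEN_SEX_LABELS.values())) == 9
        statuses = {"NS", "F_biased", "M_biased"}
        assert set(BETWEEN_SEX_LABELS) == {(c, p) for c in statuses for p in statuses}

    def test_spec_cases(self):
        labels = classify_between_sex(
            np.array([1.0, 0.5, 0.2]),
            np.array([True, False, False]),
            np.array([0.8, -1.2, 0.3]),
            np.array([True, True, False]),
        )
        assert list(labels) == ["maintained_F", "gained_M", "unbiased"]

    def test_all_nine_labels_reachable(self):
        cases = {
            ("maintained_F", (1, True, 1, True)),
            ("maintained_M", (-1, True, -1, True)),
            ("gained_F", (1, False, 1, True)),
            ("gained_M", (0.1, False, -1, True)),
            ("lost_F", (1, True, 0.3, False)),
            ("lost_M", (-1, True, -0.3, False)),
            ("reversed_F_to_M", (1, True, -1, True)),
            ("reversed_M_to_F", (-1, True, 1, True)),
            ("unbiased", (1, False, -1, False)),
        }
        for expected, (cf, cs, pf, ps) in cases:
            got = classify_between_sex(
                np.array([cf]), np.array([cs]), np.array([pf]), np.array([ps])
            )[0]
            assert got == expected

    def test_exact_zero_fold_change_maps_to_ns_defensively(self):
        labels = classify_between_sex(
            np.array([0.0]), np.array([True]), np.array([0.0]), np.array([True])
        )
        assert labels[0] == "unbiased"

    def test_labels_partition_regions(self):
        rng = np.random.default_rng(SEED)
        n = 500
        labels = classify_between_sex(
            rng.normal(size=n), rng.random(n) < 0.4,
            rng.normal(size=n), rng.random(n) < 0.4,
        )
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == n
        assert set(counts.index) <= set(BIAS_LABELS)

    def test_tightening_fdr_only_moves_toward_ns(self):
        rng = np.random.default_rng(SEED + 3)
        n = 400
        ctrl_fc, pert_fc = rng.normal(size=n), rng.normal(size=n)
        p_ctrl, p_pert = rng.random(n) * 0.1, rng.random(n) * 0.1
        for loose, tight in [(0.05, 0.01), (0.01, 0.0001)]:
            lab_loose = classify_between_sex(
                ctrl_fc, p_ctrl < loose, pert_fc, p_pert < loose
            )
            lab_tight = classify_between_sex(
                ctrl_fc, p_ctrl < tight, pert_fc, p_pert < tight
            )
            inverse = {v: k for k, v in BETWEEN_SEX_LABELS.items()}
            for lt, ll in zip(lab_tight, lab_loose):
                for st_, sl in zip(inverse[lt], inverse[ll]):
                    assert st_ in (sl, "NS")


class TestWithinSexClassification:
    def test_label_map_is_complete(self):
        assert len(WITHIN_SEX_LABELS) == 9
        assert len(set(WITHIN_SEX_LABELS.values())) == 9

    def test_up_means_higher_under_perturbation(self):
        # contrasts are control minus perturbed: negative ln_fc == induced
        labels = classify_within_sex(
            np.array([-1.0, 1.0, -1.0]),
            np.array([True, True, True]),
            np.array([-0.5, 0.0, 0.7]),
            np.array([True, False, True]),
        )
        assert list(labels) == ["both_up", "male_only_down", "opposing_MupFdown"]


class TestRollup:
    def test_single_label_gene(self):
        out = rollup_gene(
            pd.Series(["gained_F", "unbiased", "unbiased"]),
            pd.Series(["G1", "G1", "G1"]),
        )
        assert out["G1"].categories == frozenset({"gained_F"})
        assert out["G1"].n_exons_per_label == {"gained_F": 1}

    def test_multi_category_gene(self):
        out = rollup_gene(
            pd.Series(["gained_F", "maintained_M"]), pd.Series(["G1", "G1"])
        )
        assert out["G1"].categories == frozenset({"gained_F", "maintained_M"})

    def test_all_unbiased_gene_has_empty_set(self):
        out = rollup_gene(pd.Series(["unbiased", "unbiased"]), pd.Series(["G1", "G1"]))
        assert out["G1"].categories == frozenset()


class TestTabulate:
    def _assignments(self, n_sig, label="gained_F"):
        return {
            f"G{i}": GeneCategoryAssignment(f"G{i}", frozenset({label}), {label: 1})
            for i in range(n_sig)
        }

    def test_percentage_of_tested_genes(self):
        table = tabulate_landscape(self._assignments(4672), n_tested_genes=8405)
        union = table[table["category"] == "significant_union"].iloc[0]
        assert union["n_genes"] == 4672
        assert union["pct_of_tested"] == 55.6

    def test_twofold_percentage_of_significant(self):
        assignments = self._assignments(2980)
        twofold = {f"G{i}" for i in range(812)}
        table = tabulate_landscape(
            assignments, n_tested_genes=8405, twofold_genes=twofold
        )
        union = table[table["category"] == "significant_union"].iloc[0]
        assert union["pct_of_tested"] == 35.5
        assert union["n_twofold"] == 812
        assert percent(int(union["n_twofold"]), int(union["n_genes"])) == 27.2

    def test_zero_significant(self):
        table = tabulate_landscape({}, n_tested_genes=100)
        union = table[table["category"] == "significant_union"].iloc[0]
        assert union["n_genes"] == 0 and union["pct_of_tested"] == 0.0

    def test_more_significant_than_tested_rejected(self):
        with pytest.raises(ValueError, match="n_tested"):
            tabulate_landscape(self._assignments(10), n_tested_genes=5)

    def test_resolved_counts_use_priority_once_per_gene(self):
        assignments = {
            "G1": GeneCategoryAssignment(
                "G1",
                frozenset({"maintained_F", "gained_M"}),
                {"maintained_F": 1, "gained_M": 2},
            ),
            "G2": GeneCategoryAssignment("G2", frozenset({"gained_M"}), {"gained_M": 1}),
        }
        table = tabulate_landscape(assignments, n_tested_genes=10).set_index("category")
        # multi-assignment counts G1 twice; resolved counts it only as maintained_F
        assert table.loc["maintained_F", "n_genes"] == 1
        assert table.loc["gained_M", "n_genes"] == 2
        assert table.loc["maintained_F", "n_genes_resolved"] == 1
        assert table.loc["gained_M", "n_genes_resolved"] == 1
        assert (
            table["n_genes_resolved"].drop("significant_union").sum()
            == table.loc["significant_union", "n_genes"]
        )


class TestPercent:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (4672, 8405, 55.6),
            (1289, 4672, 27.6),
            (2980, 8405, 35.5),
            (812, 2980, 27.2),
            (0, 100, 0.0),
            (1, 2000, 0.1),  # 0.05% rounds half-up to 0.1
            (100, 100, 100.0),
        ],
    )
    def test_round_half_up_one_decimal(self, num, den, expected):
        assert percent(num, den) == expected

    def test_empty_denominator(self):
        assert percent(5, 0) == 0.0


class TestFoldChangePlots:
    def test_scatter_table_and_figure(self, planted_run):
        results = planted_run["results"]
        for which in ("within", "between"):
            table = results.fold_change_table(which, fdr=0.01)
            assert {"region_id", "ln_fc_x", "ln_fc_y", "label"} <= set(table.columns)
            assert len(table) == results.n_tested_regions
            fig = results.plot_fold_change(which, fdr=0.01)
            assert len(fig.axes) == 4  # scatter + two marginals (+ blank)
            import matplotlib.pyplot as plt

            plt.close(fig)


class TestEndToEndRecovery:
    def test_planted_labels_recovered_on_easy_regions(self, planted_run):
        # moderate-sized smoke check; the full criterion runs in acceptance
        results = planted_run["results"]
        truth = planted_run["truth"]
        classified = results.classify_between_sex(0.01)
        joined = classified.join(truth["planted_category"])
        non_null = joined[joined["planted_category"] != "unbiased"]
        rate = (non_null["label"] == non_null["planted_category"]).mean()
        assert rate > 0.8
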