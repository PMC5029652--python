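"""DE detection, interaction classification and summaries."""

import numpy as np
import pandas as pd
import pytest

import blisscreen as bs
from blisscreen.errors import DomainError, SchemaError
from blisscreen.transcriptomics import CONDITIONS


def make_experiment(cond_means, sigma=0.1, n_rep=3, n_null=50, seed=0):
    """One gene with the given condition means on top of ``n_null`` genes
    at a flat baseline."""
    rng = np.random.default_rng(seed)
    genes = ["target"] + [f"null{i:03d}" for i in range(n_null)]
    means = np.full((n_null + 1, 4), 8.0)
    means[0] = [cond_means[c] for c in CONDITIONS]
    data, design = {}, []
    for j, cond in enumerate(CONDITIONS):
        for rep in range(1, n_rep + 1):
            name = f"{cond}_{rep}"
            data[name] = means[:, j] + rng.normal(0, sigma, n_null + 1)
            design.append({"sample": name, "condition": cond, "replicate": rep})
    return bs.ExpressionExperiment(
        pd.DataFrame(data, index=genes), pd.DataFrame(design)
    )


class TestDetectDE:
    def test_planted_shift_detected(self):
        exp = make_experiment(
            {"vehicle": 8, "drug_a": 12, "drug_b": 12, "combination": 16},
            sigma=0.1, n_rep=3,
        )
        de = bs.detect_de(exp, alpha=0.05)
        assert bool(de.loc["target", "de_flag"])

    def test_all_identical_values_give_zero_de(self):
        exp = make_experiment(
            {c: 8.0 for c in CONDITIONS}, sigma=0.0, n_rep=2, n_null=10
        )
        de = bs.detect_de(exp)
        assert not de["de_flag"].any()
        assert de["degenerate"].all()

    def test_null_false_discovery_controlled(self):
        """Across repeats of an all-null experiment the realized
        false-discovery proportion stays at or below the FDR level."""
        fdp = []
        for seed in range(20):
            exp, _ = bs.simulate_expression(
                n_genes=500, n_de=0, n_pos=0, n_neg=0, n_rep=3, seed=seed
            )
            de = bs.detect_de(exp, alpha=0.05)
            fdp.append(de["de_flag"].mean())
        assert np.mean(fdp) <= 0.05

    def test_too_few_replicates_error(self):
        exp = make_experiment({c: 8.0 for c in CONDITIONS}, n_rep=2)
        exp.design = exp.design[~((exp.design["condition"] == "drug_a")
                                  & (exp.design["replicate"] == 2))]
        with pytest.raises(DomainError, match="replicates"):
            bs.detect_de(exp)

    def test_missing_condition_rejected(self):
        exp = make_experiment({c: 8.0 for c in CONDITIONS}, n_rep=2)
        design = exp.design[exp.design["condition"] != "combination"]
        with pytest.raises(SchemaError, match="combination"):
            bs.ExpressionExperiment(exp.matrix, design)


class TestClassifyProfiles:
    def run(self, cond_means, sigma=0.1, n_rep=3, seed=0, alpha=0.05):
        exp = make_experiment(cond_means, sigma=sigma, n_rep=n_rep, seed=seed)
        de = bs.detect_de(exp, alpha)
        return bs.classify_profiles(de, exp, alpha), exp

    def test_combo_specific_repression_is_negative_interaction(self):
        calls, _ = self.run(
            {"vehicle": 8, "drug_a": 8, "drug_b": 8, "combination": 6}
        )
        row = calls.loc["target"]
        assert row["interaction_sign"] == "negative"
        assert row["effect"] == pytest.approx(-2.0, abs=0.3)
        assert row["profile_label"].startswith("C<")

    def test_exactly_additive_combo_is_not_an_interaction(self):
        calls, _ = self.run(
            {"vehicle": 8, "drug_a": 10, "drug_b": 11, "combination": 13}
        )
        row = calls.loc["target"]
        assert row["de_flag"] and row["interaction_sign"] == "none"

    def test_superadditive_combo_is_positive(self):
        calls, _ = self.run(
            {"vehicle": 8, "drug_a": 10, "drug_b": 10, "combination": 15}
        )
        assert calls.loc["target", "interaction_sign"] == "positive"

    def test_sign_invariant_under_drug_label_swap(self):
        exp = make_experiment(
            {"vehicle": 8, "drug_a": 10, "drug_b": 9, "combination": 14}
        )
        swapped_design = exp.design.replace(
            {"condition": {"drug_a": "drug_b", "drug_b": "drug_a"}}
        )
        swapped = bs.ExpressionExperiment(exp.matrix, swapped_design)
        calls1 = bs.classify_profiles(bs.detect_de(exp), exp)
        calls2 = bs.classify_profiles(bs.detect_de(swapped), swapped)
        pd.testing.assert_series_equal(
            calls1["interaction_sign"], calls2["interaction_sign"]
        )

    def test_planted_recovery_and_conservation(self):
        exp, truth = bs.simulate_expression(
            n_genes=800, n_de=400, n_pos=100, n_neg=100,
            effect=2.0, sigma=0.25, n_rep=3, seed=123,
        )
        de = bs.detect_de(exp, 0.05)
        calls = bs.classify_profiles(de, exp, 0.05)
        summary = bs.summarize_interactions(calls)
        assert summary.n_positive + summary.n_negative == summary.n_interaction
        planted = truth["interaction"] != "none"
        correct = (
            calls.loc[planted.index[planted], "interaction_sign"]
            == truth.loc[planted, "interaction"]
        )
        assert correct.mean() >= 0.90
        nulls = truth.index[~planted]
        miscalls = (calls.loc[nulls, "interaction_sign"] != "none").mean()
        assert miscalls <= 0.05

    def test_recovery_nondecreasing_in_effect_size(self):
        rates = []
        for effect in (0.5, 1.0, 2.0, 4.0):
            exp, truth = bs.simulate_expression(
                n_genes=600, n_de=300, n_pos=100, n_neg=100,
                effect=effect, sigma=0.25, n_rep=3, seed=9,
            )
            calls = bs.classify_profiles(bs.detect_de(exp), exp)
            planted = truth["interaction"] != "none"
            rates.append(
                (calls.loc[planted.index[planted], "interaction_sign"]
                 == truth.loc[planted, "interaction"]).mean()
            )
        assert all(b >= a - 0.02 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.95

    def test_degenerate_gene_flagged_not_crashed(self):
        exp = make_experiment({c: 8.0 for c in CONDITIONS}, sigma=0.1, n_rep=2)
        exp.matrix.loc["null000"] = 5.0  # constant gene
        de = bs.detect_de(exp)
        assert bool(de.loc["null000", "degenerate"])


class TestSummary:
    def test_counts_and_percentages(self):
        s = bs.InteractionSummary.from_counts(1897, 301, 138)
        assert s.n_negative == 163
        assert round(s.pct_interaction, 1) == 15.9

    def test_top_profile_share(self):
        s = bs.InteractionSummary.from_counts(1897, 301, 138)
        s.profile_counts = {"C<V=A=B": 60, "C<A<B<V": 40}
        label, count, pct = s.top_profile
        assert (label, count) == ("C<V=A=B", 60)
        assert round(pct, 1) == 19.9

    def test_empty_calls_summarize_to_zero(self):
        calls = pd.DataFrame(
            columns=["de_flag", "interaction_sign", "profile_label"]
        ).astype({"de_flag": bool})
        s = bs.summarize_interactions(calls)
        assert (s.n_de, s.n_interaction, s.pct_interaction) == (0, 0, 0.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            bs.InteractionSummary(100, 50, 20, 10)

    def test_gene_list_export(self, tmp_path):
        exp, _ = bs.simulate_expression(
            n_genes=200, n_de=80, n_pos=20, n_neg=20, n_rep=3, seed=4
        )
        calls = bs.classify_profiles(bs.detect_de(exp), exp)
        paths = bs.export_gene_lists(calls, tmp_path)
        assert all(p.exists() for p in paths)
        pos = (tmp_path / "positive_interactions.txt").read_text().split()
        assert len(pos) == (calls["interaction_sign"] == "positive").sum()
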