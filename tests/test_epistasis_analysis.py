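import math

import numpy as np
import pytest

from kinepi.analytic_km import km_epsilon
from kinepi.epistasis_analysis import (
    DEFAULT_THRESHOLDS,
    classify,
    epsilon,
    null_predicted,
    records_frame,
    summarize,
)
from kinepi.mechanism_core import (
    RateConstantSet,
    ValidationError,
    kinetic_parameters,
)
from kinepi.mutation_simulator import build_variant_table, sample_mutations


class TestNullPredicted:
    def test_product_of_folds(self):
        assert null_predicted(10, 20, 30) == pytest.approx(60.0, rel=1e-12)

    def test_neutral_mutation(self):
        assert null_predicted(7.0, 7.0, 3.5) == pytest.approx(3.5, rel=1e-12)

    def test_km_worked_case(self, simple_wt_rates):
        """Two mutants each scaling k-1 by 0.1: predicted K_M ~ 14.8 uM."""
        wt = kinetic_parameters(simple_wt_rates)
        mutant = kinetic_parameters(
            RateConstantSet(
                "simple", simple_wt_rates.k1, simple_wt_rates.k_minus1 * 0.1, simple_wt_rates.k2
            )
        )
        predicted = null_predicted(wt.KM, mutant.KM, mutant.KM)
        assert predicted == pytest.approx(14.8e-6, rel=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            null_predicted(0.0, 1.0, 1.0)


class TestEpsilon:
    def test_equal_inputs(self):
        assert epsilon(3.2, 3.2) == pytest.approx(1.0, rel=1e-12)

    def test_km_worked_case(self, simple_wt_rates):
        """Observed double (k-1 x0.01) vs null from the two k-1 x0.1 singles."""
        k1, km1, k2 = simple_wt_rates.k1, simple_wt_rates.k_minus1, simple_wt_rates.k2
        wt = kinetic_parameters(simple_wt_rates)
        single = kinetic_parameters(RateConstantSet("simple", k1, km1 * 0.1, k2))
        double = kinetic_parameters(RateConstantSet("simple", k1, km1 * 0.01, k2))
        eps = epsilon(double.KM, null_predicted(wt.KM, single.KM, single.KM))
        assert eps == pytest.approx(2.84, rel=0.01)
        # matches the closed form with alpha=0.1, beta=gamma=1 for both
        assert eps == pytest.approx(km_epsilon(0.1, 1, 0.1, 1, km1, k2), rel=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            epsilon(-1.0, 2.0)


class TestClassify:
    def test_multiplicative_pair_not_significant(self):
        assert classify(1, 2, 2, 4, 1.5) == ("none", "none")

    def test_positive_magnitude(self):
        assert classify(1, 2, 2, 8, 1.5) == ("positive", "magnitude")

    def test_negative_sign_under_strict_rule(self):
        # mutation 1's effect flips (2 -> 0.8) while mutation 2's does not
        assert classify(1, 2, 3, 2.4, 1.5, flip_rule="strict") == ("negative", "sign")

    def test_negative_reciprocal_under_strict_rule(self):
        # both effects flip (2 -> 0.75)
        assert classify(1, 2, 2, 1.5, 1.5, flip_rule="strict") == (
            "negative",
            "reciprocal_sign",
        )

    def test_thresholded_rule_ignores_sub_threshold_flips(self):
        # the flipped background effects (0.8, 0.75) are inside the 1.5-fold
        # noise band, so the default rule calls both magnitude
        assert classify(1, 2, 3, 2.4, 1.5) == ("negative", "magnitude")
        assert classify(1, 2, 2, 1.5, 1.5) == ("negative", "magnitude")

    def test_thresholded_rule_detects_genuine_flips(self):
        # each single doubles the parameter; the double drops it 4-fold below
        # wt, so each effect is significantly deleterious in the other
        # background: reciprocal sign
        assert classify(1, 2, 2, 0.25, 1.5) == ("negative", "reciprocal_sign")

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValidationError):
            classify(1, 2, 2, 8, 1.0)

    def test_unknown_flip_rule(self):
        with pytest.raises(ValidationError):
            classify(1, 2, 2, 8, 1.5, flip_rule="bogus")


class TestExactNullInvariants:
    def test_simple_kcat_and_kd_never_epistatic(self, small_simple_table):
        for param in ("kcat", "KD"):
            eps = small_simple_table.pair_params[param] / small_simple_table.pair_null[param]
            np.testing.assert_allclose(eps, 1.0, rtol=1e-10)

    def test_complex_kd_never_epistatic(self, small_complex_table):
        eps = small_complex_table.pair_params["KD"] / small_complex_table.pair_null["KD"]
        np.testing.assert_allclose(eps, 1.0, rtol=1e-10)

    def test_complex_kcat_generically_epistatic(self, small_complex_table):
        eps = small_complex_table.pair_params["kcat"] / small_complex_table.pair_null["kcat"]
        assert np.abs(np.log(eps)).max() > math.log(1.5)

    def test_simple_km_efficiency_epsilons_reciprocal(self, small_simple_table):
        eps_km = small_simple_table.pair_params["KM"] / small_simple_table.pair_null["KM"]
        eps_eff = (
            small_simple_table.pair_params["efficiency"]
            / small_simple_table.pair_null["efficiency"]
        )
        np.testing.assert_allclose(eps_km * eps_eff, 1.0, rtol=1e-10)

    def test_pipeline_epsilon_matches_closed_form(self, small_simple_table):
        """epsilon(K_M) from the simulation equals the closed form evaluated
        on the singles' k-1 and k2 fold-changes."""
        t = small_simple_table
        alpha = t.single_rate_folds["k_minus1"]
        beta = t.single_rate_folds["k2"]
        predicted = km_epsilon(
            alpha[t.pair_i],
            beta[t.pair_i],
            alpha[t.pair_j],
            beta[t.pair_j],
            t.wt_rates["k_minus1"],
            t.wt_rates["k2"],
        )
        observed = t.pair_params["KM"] / t.pair_null["KM"]
        np.testing.assert_allclose(observed, predicted, rtol=1e-8)


class TestSummarize:
    def test_counts_and_share_arithmetic(self, small_simple_table):
        summary = summarize(small_simple_table)
        assert summary.n_pairs == 780
        for param in ("kcat", "KM", "KD", "efficiency"):
            shares = summary.class_shares_pct[param]
            prevalence = summary.prevalence_pct[param][1.5]
            assert sum(shares.values()) == pytest.approx(prevalence, abs=1e-9)
            signs = summary.sign_shares_pct[param]
            if summary.counts[param]["significant"]["1.5"] > 0:
                assert signs["positive"] + signs["negative"] == pytest.approx(100.0)

    def test_prevalence_monotone_in_threshold(self, small_complex_table):
        summary = summarize(small_complex_table)
        for param in ("kcat", "KM", "efficiency"):
            values = [summary.prevalence_pct[param][t] for t in DEFAULT_THRESHOLDS]
            assert values == sorted(values, reverse=True)

    def test_exact_null_parameters_have_zero_prevalence(self, small_simple_table):
        summary = summarize(small_simple_table)
        for param in ("kcat", "KD"):
            assert all(v == 0.0 for v in summary.prevalence_pct[param].values())

    def test_km_sign_shares_mirror_efficiency(self, small_simple_table):
        """epsilon(K_M) = 1/epsilon(efficiency) per pair, so positive and
        negative shares swap between the two parameters."""
        summary = summarize(small_simple_table)
        assert summary.sign_shares_pct["KM"]["positive"] == pytest.approx(
            summary.sign_shares_pct["efficiency"]["negative"], abs=1e-9
        )

    def test_single_nonepistatic_pair(self, simple_profile):
        effects = sample_mutations(2, (-2, 2), "simple", seed=30)
        # overwrite to a uniform shift: no epistasis anywhere
        from kinepi.mutation_simulator import MutationEffect

        uniform = [
            MutationEffect(i, {s: 0.5 for s in simple_profile.states}) for i in (0, 1)
        ]
        table = build_variant_table(simple_profile, uniform)
        summary = summarize(table)
        for param in ("kcat", "KM", "KD", "efficiency"):
            assert all(v == 0.0 for v in summary.prevalence_pct[param].values())

    def test_invalid_thresholds_rejected(self, small_simple_table):
        with pytest.raises(ValidationError):
            summarize(small_simple_table, thresholds=[1.0, 2.0])


class TestRecordsFrame:
    def test_layout_and_consistency_with_scalar_classify(self, small_simple_table):
        frame = records_frame(small_simple_table)
        assert len(frame) == 4 * 780
        assert set(frame["parameter"]) == {"kcat", "KM", "KD", "efficiency"}
        # spot-check rows against the scalar classifier
        t = small_simple_table
        sub = frame[frame["parameter"] == "efficiency"].reset_index(drop=True)
        for k in range(0, 780, 97):
            i, j = t.pair_i[k], t.pair_j[k]
            sign, kind = classify(
                t.wt_params["efficiency"],
                t.single_params["efficiency"][i],
                t.single_params["efficiency"][j],
                t.pair_params["efficiency"][k],
            )
            assert sub.loc[k, "sign"] == sign
            assert sub.loc[k, "type"] == kind

    def test_epsilon_column_matches_ratio(self, small_complex_table):
        frame = records_frame(small_complex_table)
        np.testing.assert_allclose(
            frame["epsilon"], frame["observed_fold"] / frame["predicted_fold"], rtol=1e-9
        )
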