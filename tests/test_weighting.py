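"""Raking to population margins and weighted-refit comparisons."""

import numpy as np
import pandas as pd
import pytest

from eqvalue.fitting import FitOptions, fit_model
from eqvalue.models import ModelSpec
from eqvalue.state_space import CoefficientSet, DIMENSIONS
from eqvalue.synthetic_data import DEFAULT_TRUTH, TruePreferences, simulate_study
from eqvalue.weighting import (
    compute_weights,
    read_margins,
    weighted_refit_delta,
    write_margins,
)


def _weighted_share(demo, w, char, cat):
    return w[(demo[char] == cat).to_numpy()].sum() / w.sum()


class TestRaking:
    def test_sample_already_at_margins_gives_unit_weights(self):
        demo = pd.DataFrame({"sex": ["f"] * 50 + ["m"] * 50})
        w = compute_weights(demo, {"sex": {"f": 0.5, "m": 0.5}})
        np.testing.assert_allclose(w.to_numpy(), 1.0)

    def test_single_binary_characteristic_closed_form(self):
        # sample 75/25 against a 50/50 target: raw ratios 2/3 and 2,
        # which already have mean 1 under the sample distribution
        demo = pd.DataFrame({"sex": ["f"] * 75 + ["m"] * 25})
        w = compute_weights(demo, {"sex": {"f": 0.5, "m": 0.5}})
        np.testing.assert_allclose(w[:75], 2.0 / 3.0, atol=1e-9)
        np.testing.assert_allclose(w[75:], 2.0, atol=1e-9)

    def test_converged_margins_match_targets(self):
        rng = np.random.default_rng(3)
        demo = pd.DataFrame(
            {
                "sex": rng.choice(["f", "m"], p=[0.7, 0.3], size=600),
                "age": rng.choice(["y", "mid", "old"], p=[0.5, 0.3, 0.2], size=600),
                "region": rng.choice(["a", "b"], p=[0.6, 0.4], size=600),
            }
        )
        margins = {
            "sex": {"f": 0.5, "m": 0.5},
            "age": {"y": 0.3, "mid": 0.5, "old": 0.2},
            "region": {"a": 0.45, "b": 0.55},
        }
        w = compute_weights(demo, margins)
        wv = w.to_numpy()
        for char, cats in margins.items():
            for cat, p in cats.items():
                assert _weighted_share(demo, wv, char, cat) == pytest.approx(p, abs=1e-6)
        assert wv.mean() == pytest.approx(1.0, abs=1e-12)
        assert (wv > 0).all()

    def test_order_invariance_on_crossed_toy(self):
        rng = np.random.default_rng(4)
        demo = pd.DataFrame(
            {
                "a": rng.choice(["0", "1"], p=[0.6, 0.4], size=400),
                "b": rng.choice(["0", "1"], p=[0.7, 0.3], size=400),
                "c": rng.choice(["0", "1"], p=[0.45, 0.55], size=400),
            }
        )
        margins = {k: {"0": 0.5, "1": 0.5} for k in "abc"}
        w1 = compute_weights(demo, margins, characteristics=["a", "b", "c"])
        w2 = compute_weights(demo, margins, characteristics=["c", "a", "b"])
        np.testing.assert_allclose(w1.to_numpy(), w2.to_numpy(), atol=1e-9)

    def test_empty_cell_with_nonzero_margin_raises(self):
        demo = pd.DataFrame({"sex": ["f"] * 10})
        with pytest.raises(ValueError, match="empty sample cell"):
            compute_weights(demo, {"sex": {"f": 0.5, "m": 0.5}})

    def test_unlisted_category_keeps_share_and_positive_weight(self):
        demo = pd.DataFrame({"sex": ["f"] * 60 + ["m"] * 38 + ["other"] * 2})
        w = compute_weights(demo, {"sex": {"f": 0.498, "m": 0.502}})
        assert (w > 0).all()
        # listed categories hit the rescaled targets; "other" keeps its share
        wv = w.to_numpy()
        assert _weighted_share(demo, wv, "sex", "other") == pytest.approx(0.02, abs=1e-6)

    def test_logistic_variant_agrees_with_raking(self):
        rng = np.random.default_rng(5)
        demo = pd.DataFrame({"sex": rng.choice(["f", "m"], p=[0.7, 0.3], size=500)})
        margins = {"sex": {"f": 0.5, "m": 0.5}}
        w_rake = compute_weights(demo, margins)
        w_log = compute_weights(demo, margins, method="logistic")
        np.testing.assert_allclose(w_rake.to_numpy(), w_log.to_numpy(), rtol=0.05)

    def test_margins_file_round_trip(self, tmp_path):
        margins = {"sex": {"f": 0.498, "m": 0.502}, "age": {"y": 0.3, "o": 0.7}}
        path = tmp_path / "margins.csv"
        write_margins(margins, path)
        assert read_margins(path) == margins


class TestWeightedRefit:
    def test_identical_weights_give_zero_delta(self, small_study, fast_options):
        spec = ModelSpec()
        fit = fit_model(spec, small_study, options=fast_options, compute_metrics=False)
        delta = weighted_refit_delta(fit, fit)
        assert (delta["delta"].abs() < 1e-15).all()

    def test_independent_demographics_weighting_changes_little(self, small_study, fast_options):
        # demographics carry no preference information, so re-weighting moves
        # coefficients by at most sampling noise
        spec = ModelSpec()
        unw = fit_model(spec, small_study, options=fast_options, compute_metrics=False)
        w = compute_weights(
            small_study.respondents,
            {"sex": {"female": 0.5, "male": 0.5}},
            characteristics=["sex"],
        )
        w = pd.Series(w.to_numpy(), index=small_study.respondents["id"].to_numpy())
        wf = fit_model(spec, small_study, weights=w, options=fast_options, compute_metrics=False)
        delta = weighted_refit_delta(unw, wf)
        structural = list(DIMENSIONS) + ["L2", "L3", "L4"]
        assert delta.loc[structural, "delta"].abs().max() < 0.03

    def test_confounded_sampling_corrected_by_weighting(self):
        # two latent preference groups: older respondents weight AD twice as
        # much; the sample over-represents the young 4:1 while the population
        # is 50/50.  Raking to age must move beta_AD toward the population mean.
        base = DEFAULT_TRUTH.coeffs
        young = base
        old = CoefficientSet(
            form="multiplicative8",
            beta={**base.beta, "AD": base.beta["AD"] * 2.0},
            levels=dict(base.levels),
        )
        parts = []
        rng_ids = iter(range(10**6))
        for coeffs, n, label in ((young, 480, "young"), (old, 120, "old")):
            truth = TruePreferences(coeffs, tau=0.1, sigma_a=0.2, sigma_b=0.05)
            ds = simulate_study(truth, n_respondents=n, seed=60 + len(parts))
            offset = 0 if label == "young" else 10**5
            for df in (ds.ctto, ds.dce):
                df["respondent_id"] += offset
            ds.respondents["id"] += offset
            ds.respondents["age_group"] = label
            parts.append(ds)
        from eqvalue.synthetic_data import InterviewDataset

        merged = InterviewDataset(
            ctto=pd.concat([p.ctto for p in parts], ignore_index=True),
            dce=pd.concat([p.dce for p in parts], ignore_index=True),
            respondents=pd.concat([p.respondents for p in parts], ignore_index=True),
        )
        opts = FitOptions(n_starts=1, n_quad=9)
        spec = ModelSpec()
        unw = fit_model(spec, merged, options=opts, compute_metrics=False)
        w = compute_weights(
            merged.respondents, {"age_group": {"young": 0.5, "old": 0.5}},
            characteristics=["age_group"],
        )
        w = pd.Series(w.to_numpy(), index=merged.respondents["id"].to_numpy())
        wf = fit_model(spec, merged, weights=w, options=opts, compute_metrics=False)
        pop_truth_ad = 0.5 * base.beta["AD"] + 0.5 * base.beta["AD"] * 2.0
        ad_unw = unw.coefficient_series()["AD"]
        ad_w = wf.coefficient_series()["AD"]
        assert abs(ad_w - pop_truth_ad) < abs(ad_unw - pop_truth_ad)
        assert ad_w > ad_unw  # weighting pulls toward the under-sampled group
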