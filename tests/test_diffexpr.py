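"""Median-of-ratios size factors, MoM dispersion, exact NB test, DE calls."""

import numpy as np
import pandas as pd
import pytest

from lncforge.diffexpr import (
    NBModel,
    call_de,
    estimate_dispersion,
    exact_nb_pvalue,
    fit_nb_model,
    nb_test,
    size_factors,
)
from lncforge.errors import ConfigurationError, EstimationError
from lncforge.models import SampleSheet


def _sheet(n_per_group=3, phase="follicular"):
    cols = [f"A{i}" for i in range(n_per_group)] + [f"B{i}" for i in range(n_per_group)]
    return cols, SampleSheet(pd.DataFrame({
        "sample_id": cols,
        "group": ["monotocous"] * n_per_group + ["polytocous"] * n_per_group,
        "phase": [phase] * (2 * n_per_group),
    }))


def test_size_factors_worked_matrix():
    counts = pd.DataFrame([[1, 2], [2, 4], [3, 6]], columns=["s1", "s2"])
    sf = size_factors(counts)
    assert sf["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
    assert sf["s2"] == pytest.approx(np.sqrt(2), abs=1e-12)


def test_size_factors_identical_columns_are_one():
    counts = pd.DataFrame([[5, 5, 5], [9, 9, 9]], columns=list("abc"))
    assert np.allclose(size_factors(counts), 1.0)


def test_size_factor_scales_with_column():
    rng = np.random.default_rng(0)
    for _ in range(20):
        counts = pd.DataFrame(rng.integers(1, 1000, size=(50, 4)),
                              columns=list("abcd"))
        sf = size_factors(counts)
        scaled = counts.copy()
        scaled["c"] *= 3
        sf2 = size_factors(scaled)
        # size factors are defined up to a common scale: the scaled column's
        # factor grows by exactly 3 relative to every other column
        assert sf2["c"] / sf2["a"] == pytest.approx(3 * sf["c"] / sf["a"], rel=1e-12)
        assert sf2["b"] / sf2["a"] == pytest.approx(sf["b"] / sf["a"], rel=1e-12)


def test_size_factors_need_an_all_positive_feature():
    counts = pd.DataFrame([[0, 5], [5, 0]], columns=["s1", "s2"])
    with pytest.raises(EstimationError, match="nonzero"):
        size_factors(counts)


def test_dispersion_zero_for_constant_counts():
    cols, _ = _sheet()
    counts = pd.DataFrame([[7] * 6], columns=cols)
    sf = pd.Series(1.0, index=cols)
    cond = pd.Series(["A"] * 3 + ["B"] * 3, index=cols)
    disp = estimate_dispersion(counts, sf, cond)
    assert disp.iloc[0] == pytest.approx(1e-8)


def test_dispersion_vanishes_for_poisson_data():
    rng = np.random.default_rng(1)
    n = 200
    cols = [f"s{i}" for i in range(2 * n)]
    counts = pd.DataFrame(rng.poisson(100, size=(300, 2 * n)), columns=cols)
    sf = pd.Series(1.0, index=cols)
    cond = pd.Series(["A"] * n + ["B"] * n, index=cols)
    disp = estimate_dispersion(counts, sf, cond)
    assert disp.mean() < 0.01


def test_dispersion_requires_replication():
    cols = ["a", "b"]
    counts = pd.DataFrame([[1, 2]], columns=cols)
    sf = pd.Series(1.0, index=cols)
    cond = pd.Series(["A", "B"], index=cols)
    with pytest.raises(EstimationError, match="replicates"):
        estimate_dispersion(counts, sf, cond)


def test_identical_groups_give_p_one_and_ns():
    cols, sheet = _sheet()
    counts = pd.DataFrame([[10, 20, 30, 10, 20, 30],
                           [100, 90, 110, 100, 90, 110]], columns=cols)
    res = call_de(nb_test(counts, fit_nb_model(counts, sheet, "follicular")))
    assert np.allclose(res["pvalue"], 1.0)
    assert (res["call"] == "ns").all()
    assert np.allclose(res["fold_change"], 1.0)


def test_label_exchange_inverts_fold_change_keeps_p():
    cols, sheet = _sheet()
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(rng.integers(5, 500, size=(40, 6)), columns=cols)
    model = fit_nb_model(counts, sheet, "follicular")
    res = nb_test(counts, model)
    swapped = NBModel(model.size_factors, model.dispersions,
                      model.samples_b, model.samples_a)
    res2 = nb_test(counts, swapped)
    assert np.allclose(res2["fold_change"], 1.0 / res["fold_change"])
    assert np.allclose(res2["pvalue"], res["pvalue"])


def test_zero_in_both_groups_flagged():
    cols, sheet = _sheet()
    counts = pd.DataFrame([[0] * 6, [50, 60, 40, 55, 45, 60]], columns=cols)
    res = nb_test(counts, fit_nb_model(counts, sheet, "follicular"))
    row = res.iloc[0]
    assert row["pvalue"] == 1.0 and row["fold_change"] == 1.0
    assert row["flag"] == "all_zero"


def test_bh_adjustment_dominates_p_and_is_monotone():
    cols, sheet = _sheet()
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(1, 300, size=(60, 6)), columns=cols)
    res = nb_test(counts, fit_nb_model(counts, sheet, "follicular"))
    assert (res["padj"] >= res["pvalue"] - 1e-15).all()
    ordered = res.sort_values("pvalue")
    assert (np.diff(ordered["padj"]) >= -1e-15).all()
    assert res["pvalue"].between(0, 1).all()


@pytest.mark.parametrize("fc,p,expect", [
    (1.6, 0.04, "up"),
    (1.6, 0.06, "ns"),
    (1.5, 0.01, "ns"),          # strict > on the threshold
    (1 / 1.6, 0.04, "down"),
    (1 / 1.5, 0.01, "ns"),
])
def test_call_rule_boundaries(fc, p, expect):
    records = pd.DataFrame({"fold_change": [fc], "pvalue": [p], "padj": [p]},
                           index=["f"])
    assert call_de(records)["call"].item() == expect


def test_call_rule_use_validation():
    records = pd.DataFrame({"fold_change": [2.0], "pvalue": [0.01], "padj": [0.01]})
    with pytest.raises(ConfigurationError):
        call_de(records, use="bogus")


def test_exact_pvalue_is_a_probability_and_symmetric():
    p = exact_nb_pvalue(10, 30, 20.0, 20.0, 60.0, 60.0)
    assert 0 <= p <= 1
    assert p == pytest.approx(exact_nb_pvalue(30, 10, 20.0, 20.0, 60.0, 60.0))


def test_scaling_invariance_of_normalized_quantities():
    """Multiplying one sample's counts by an integer leaves normalized counts
    and fold changes unchanged (size factor absorbs the scale)."""
    cols, sheet = _sheet()
    rng = np.random.default_rng(4)
    counts = pd.DataFrame(rng.integers(10, 400, size=(50, 6)), columns=cols)
    scaled = counts.copy()
    scaled["B1"] *= 4
    r1 = nb_test(counts, fit_nb_model(counts, sheet, "follicular"))
    r2 = nb_test(scaled, fit_nb_model(scaled, sheet, "follicular"))
    assert np.allclose(r1["fold_change"], r2["fold_change"], rtol=1e-10)
    # normalized means shift only by a common constant (sf scale freedom)
    ratio = r2["baseMean_A"] / r1["baseMean_A"]
    assert np.allclose(ratio, ratio.iloc[0], rtol=1e-10)
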