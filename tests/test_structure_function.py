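"""BLUP correlation matrices, exact signed-rank test, rankings."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glauprog.errors import ValidationError
from glauprog.structure_function import (CorrelationResult, best_pairs,
                                         compare_corresponding,
                                         compare_variants, correlate_blups,
                                         pearson_r, signed_rank_test,
                                         strength_category)


# ---------------------------------------------------------------------------
# strength labels

@pytest.mark.parametrize("r,label", [
    (0.358, "weak"), (-0.358, "weak"), (0.548, "moderate"),
    (0.40, "moderate"), (0.699, "moderate"), (0.7, "strong"),
    (1.0, "strong"), (0.0, "weak"), (float("nan"), "undefined"),
])
def test_strength_category(r, label):
    assert strength_category(r) == label


def test_strength_category_rejects_impossible():
    with pytest.raises(ValidationError):
        strength_category(1.2)


# ---------------------------------------------------------------------------
# exact signed-rank

def enumeration_oracle(diffs, alternative):
    """Brute force: p-value over all 2^n equiprobable sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


def test_exact_signed_rank_matches_enumeration_all_patterns_n6():
    base = np.array([0.21, 0.35, 0.07, 0.52, 0.16, 0.44])
    for signs in itertools.product([-1, 1], repeat=6):
        d = base * signs
        for alt in ("two-sided", "greater", "less"):
            got = signed_rank_test(d, alternative=alt)
            assert got.p_value == pytest.approx(
                enumeration_oracle(d, alt), abs=1e-12), (signs, alt)


def test_exact_signed_rank_with_tied_magnitudes():
    d = np.array([0.2, -0.2, 0.5, 0.5, -0.1, 0.3, 0.3, -0.5])
    for alt in ("two-sided", "greater"):
        got = signed_rank_test(d, alternative=alt)
        assert got.p_value == pytest.approx(enumeration_oracle(d, alt),
                                            abs=1e-12)


def test_all_positive_six_differences_is_one_in_sixtyfour():
    d = np.array([0.3, 0.5, 0.25, 0.45, 0.21, 0.6])
    assert signed_rank_test(d, alternative="greater").p_value == \
        pytest.approx(1 / 64)


def test_all_zero_differences_carry_no_evidence():
    out = signed_rank_test(np.zeros(6))
    assert out.p_value == 1.0 and out.n == 0


def test_exact_signed_rank_agrees_with_scipy_when_tie_free(rng):
    for _ in range(20):
        d = rng.normal(0.2, 1.0, 9)
        mine = signed_rank_test(d, alternative="two-sided")
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_large_sample_normal_branch_reasonable(rng):
    d = rng.normal(0.4, 1.0, 60)
    out = signed_rank_test(d)
    ref = sps.wilcoxon(d, alternative="two-sided", method="approx",
                       correction=False)
    assert out.detail["mode"] == "normal"
    assert out.p_value == pytest.approx(ref.pvalue, rel=0.05)


# ---------------------------------------------------------------------------
# correlation matrices

def blup_frame(rng, sectors, n=30, seed_shift=0):
    return pd.DataFrame(rng.normal(size=(n, len(sectors))),
                        index=[f"e{i}" for i in range(n)], columns=sectors)


def test_self_correlation_diagonal_is_one(rng):
    sectors = ["a", "b", "c"]
    x = blup_frame(rng, sectors)
    res = correlate_blups(x, x, which="slope", map_name="m",
                          correspondence={s: s for s in sectors})
    assert np.allclose(np.diag(res.r.to_numpy(dtype=float)), 1.0)
    assert res.n_eyes == 30
    assert res.corresponding.to_numpy().trace() == 3


def test_zero_variance_cell_is_undefined_not_zero(rng):
    x = blup_frame(rng, ["a", "b"])
    y = blup_frame(rng, ["u", "v"])
    y["u"] = 5.0
    res = correlate_blups(x, y)
    assert np.isnan(res.r.loc["a", "u"])
    assert np.isfinite(res.r.loc["a", "v"])
    assert res.category.loc["a", "u"] == "undefined"


def test_too_few_common_eyes_rejected(rng):
    x = blup_frame(rng, ["a"], n=5)
    y = blup_frame(rng, ["u"], n=5)
    y.index = [f"z{i}" for i in range(5)]
    with pytest.raises(ValidationError):
        correlate_blups(x, y)


def test_pearson_affine_invariance(rng):
    x, y = rng.normal(size=40), rng.normal(size=40)
    r = pearson_r(x, y)
    assert pearson_r(3.2 * x - 7, y) == pytest.approx(r, abs=1e-12)
    assert pearson_r(-x, y) == pytest.approx(-r, abs=1e-12)
    assert abs(pearson_r(-2 * x + 1, 0.5 * y - 4)) == pytest.approx(abs(r),
                                                                    abs=1e-12)


# ---------------------------------------------------------------------------
# corresponding vs non-corresponding comparisons

def make_result(r_matrix, sectors=("s1", "s2", "s3", "s4", "s5", "s6")):
    sectors = list(sectors)
    r = pd.DataFrame(r_matrix, index=sectors, columns=sectors, dtype=float)
    corr = pd.DataFrame(np.eye(len(sectors), dtype=bool), index=sectors,
                        columns=sectors)
    return CorrelationResult(map_name="m", which="slope", variant={},
                             r=r, n=r * 0 + 100, corresponding=corr,
                             n_eyes=100)


def test_clearly_higher_corresponding_cells_give_exact_small_p():
    base = np.full((6, 6), 0.2)
    np.fill_diagonal(base, 0.45)   # every corresponding cell +0.25
    res = make_result(base)
    out = compare_corresponding(res, alternative="greater")
    assert out.p_value == pytest.approx(1 / 64)
    assert out.n == 6


def test_identical_cells_give_p_one():
    res = make_result(np.full((6, 6), 0.3))
    out = compare_corresponding(res)
    assert out.p_value == 1.0


def test_pooled_rank_sum_scheme_runs():
    base = np.full((6, 6), 0.2)
    np.fill_diagonal(base, 0.6)
    out = compare_corresponding(make_result(base), scheme="pooled_rank_sum",
                                alternative="greater")
    assert out.test == "mann_whitney_u"
    assert out.p_value < 0.01


def test_null_p_values_are_uniform(rng):
    """Corresponding and non-corresponding cells from one distribution give
    approximately uniform p-values."""
    ps = []
    for _ in range(300):
        res = make_result(rng.normal(0.3, 0.1, size=(6, 6)))
        ps.append(compare_corresponding(res, alternative="greater").p_value)
    stat = sps.kstest(ps, "uniform")
    # discrete p-grid (n=6 exact test) inflates KS; bound loosely
    assert np.mean(np.asarray(ps) <= 0.25) == pytest.approx(0.25, abs=0.09)


def test_compare_variants_matched_cells(rng):
    a = make_result(rng.normal(0.3, 0.05, (6, 6)))
    shifted = a.r.to_numpy() + 0.1
    b = make_result(shifted)
    out = compare_variants(b, a, alternative="greater")
    assert out.p_value < 1e-6 or out.detail["mode"] == "normal"
    mismatched = make_result(np.zeros((5, 5)), sectors=list("abcde"))
    with pytest.raises(ValidationError):
        compare_variants(a, mismatched)


def test_best_pairs_ranking(rng):
    m = rng.normal(0.2, 0.05, (6, 6))
    m[1, 3] = 0.9
    res = make_result(m)
    hemis = {("m", s): ("superior" if s in ("s1", "s2", "s3") else "inferior")
             for s in res.r.index}
    table = best_pairs([res], hemis)
    top_sup = table[(table.hemifield == "superior")
                    & (table.rank_in_group == 1)].iloc[0]
    assert (top_sup.vf_sector, top_sup.oct_sector) == ("s2", "s4")
    assert top_sup.r == pytest.approx(0.9)
    with pytest.raises(ValidationError):
        best_pairs([])
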