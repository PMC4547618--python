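"""Rank-correlation evaluation statistics against independent oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from _oracles import brute_spearman, sign_test_closed_form
from amplifun import (AbundanceProfile, evaluate_paired, exclude_zero_dims,
                      sign_test, spearman)
from amplifun.errors import (AmplifunError, NoNonzeroDifferencesError,
                             ZeroRankVarianceError)


def _ko(mapping, normalized=False):
    return AbundanceProfile.from_mapping(mapping, "ko", normalized=normalized)


# --------------------------------------------------------------------------
# zero-dimension exclusion
# --------------------------------------------------------------------------

def test_dimensions_zero_in_both_are_dropped():
    a = _ko({"K1": 0.0, "K2": 0.5, "K3": 0.5, "K4": 0.0})
    b = _ko({"K1": 0.0, "K2": 0.3, "K3": 0.7, "K4": 0.0})
    ids, va, vb = exclude_zero_dims(a, b)
    assert ids == ("K2", "K3")
    np.testing.assert_array_equal(va, [0.5, 0.5])
    np.testing.assert_array_equal(vb, [0.3, 0.7])


def test_disjoint_supports_are_both_retained():
    a = _ko({"K1": 1.0})
    b = _ko({"K2": 1.0})
    ids, va, vb = exclude_zero_dims(a, b)
    assert ids == ("K1", "K2")


def test_single_retained_dimension_is_an_error():
    a = _ko({"K1": 1.0})
    with pytest.raises(AmplifunError):
        exclude_zero_dims(a, a)


def test_retained_count_monotone_under_added_mass():
    a = _ko({"K1": 1.0, "K2": 0.0, "K3": 2.0})
    b = _ko({"K1": 1.0, "K2": 0.0, "K3": 0.5})
    before = len(exclude_zero_dims(a, b)[0])
    a2 = _ko({"K1": 1.0, "K2": 0.7, "K3": 2.0})
    after = len(exclude_zero_dims(a2, b)[0])
    assert after >= before


# --------------------------------------------------------------------------
# Spearman
# --------------------------------------------------------------------------

def test_spearman_worked_values():
    assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0, abs=1e-12)
    assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8,
                                                                 abs=1e-12)
    # ties -> mid-ranks (1.5, 1.5, 3) vs (1, 2, 3)
    expected = brute_spearman([1, 1, 2], [1, 2, 3])
    assert spearman([1, 1, 2], [1, 2, 3]) == pytest.approx(expected,
                                                           abs=1e-12)
    assert expected == pytest.approx(np.sqrt(3) / 2, abs=1e-12)


def test_spearman_matches_brute_force_with_ties(rng):
    for _ in range(200):
        n = int(rng.integers(2, 51))
        x = rng.integers(0, 8, size=n).astype(float)  # heavy ties
        y = x + rng.normal(scale=2.0, size=n)
        if np.ptp(x) == 0:
            continue
        mine = spearman(x, y)
        assert mine == pytest.approx(brute_spearman(x, y), abs=1e-12)
        scipy_rho = stats.spearmanr(x, y).statistic
        assert mine == pytest.approx(scipy_rho, abs=1e-12)


def test_spearman_constant_vector_is_an_error():
    with pytest.raises(ZeroRankVarianceError):
        spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@settings(derandomize=True, max_examples=40)
@given(st.lists(st.integers(min_value=-50, max_value=50), min_size=3,
                max_size=20).filter(lambda v: len(set(v)) > 1),
       st.lists(st.integers(min_value=-50, max_value=50), min_size=3,
                max_size=20).filter(lambda v: len(set(v)) > 1))
def test_spearman_invariant_under_monotone_transform(x, y):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return
    base = spearman(x, y)
    fx = [np.exp(0.1 * v) for v in x]          # strictly increasing transform
    gy = [v ** 3 + 2.0 * v for v in y]         # strictly increasing transform
    assert spearman(fx, gy) == pytest.approx(base, abs=1e-12)


# --------------------------------------------------------------------------
# sign test
# --------------------------------------------------------------------------

def test_sign_test_worked_values():
    all_pos = sign_test([1.0] * 10)
    assert all_pos.p_value == pytest.approx(0.001953125, abs=1e-15)
    split = sign_test([1.0, -1.0])
    assert split.p_value == 1.0
    with_zeros = sign_test([1.0] * 5 + [0.0] * 5)
    assert with_zeros.n_zero == 5
    assert with_zeros.p_value == pytest.approx(0.0625, abs=1e-15)


def test_sign_test_matches_closed_form_exhaustively():
    for n in range(1, 21):
        for k in range(n + 1):
            deltas = [1.0] * k + [-1.0] * (n - k)
            assert sign_test(deltas).p_value == pytest.approx(
                sign_test_closed_form(k, n), abs=1e-14), (n, k)


def test_sign_test_all_zero_differences_is_an_error():
    with pytest.raises(NoNonzeroDifferencesError):
        sign_test([0.0, 0.0, 0.0])


# --------------------------------------------------------------------------
# paired evaluation
# --------------------------------------------------------------------------

def _sample_profiles(rng, n_samples=4, n_kos=20):
    preds, metas = {}, {}
    kos = [f"K{i:05d}" for i in range(1, n_kos + 1)]
    for s in range(n_samples):
        sid = f"s{s}"
        v = rng.random(n_kos)
        preds[sid] = AbundanceProfile(tuple(kos), v / v.sum(), "ko",
                                      normalized=True)
        w = v + rng.normal(scale=0.1, size=n_kos).clip(-0.05)
        w = np.abs(w)
        metas[sid] = AbundanceProfile(tuple(kos), w / w.sum(), "ko",
                                      normalized=True)
    return preds, metas


def test_identical_profiles_give_rho_one(rng):
    preds, _ = _sample_profiles(rng)
    report = evaluate_paired(preds, preds)
    assert all(r == 1.0 for r in report.per_sample_rho.values())
    assert report.median_rho == 1.0


def test_evaluation_is_deterministic(rng):
    preds, metas = _sample_profiles(rng)
    r1 = evaluate_paired(preds, metas)
    r2 = evaluate_paired(preds, metas)
    assert r1.per_sample_rho == r2.per_sample_rho
    assert r1.median_rho == r2.median_rho


def test_competitor_equal_to_predictions_surfaces_sign_test_error(rng):
    preds, metas = _sample_profiles(rng)
    with pytest.raises(NoNonzeroDifferencesError):
        evaluate_paired(preds, metas, competitor=preds)


def test_competitor_comparison_reports_sign_test(rng):
    preds, metas = _sample_profiles(rng, n_samples=8)
    worse = {s: AbundanceProfile(p.feature_ids,
                                 np.roll(p.values, 3), "ko",
                                 normalized=True)
             for s, p in preds.items()}
    report = evaluate_paired(preds, metas, competitor=worse)
    assert report.sign_test is not None
    assert 0.0 < report.sign_test_p <= 1.0
    assert set(report.competitor_rho) == set(report.per_sample_rho)


def test_no_shared_samples_is_an_error(rng):
    preds, metas = _sample_profiles(rng)
    renamed = {f"other_{k}": v for k, v in metas.items()}
    with pytest.raises(AmplifunError):
        evaluate_paired(preds, renamed)


def test_exclusion_scope_pair_vs_dataset():
    # K3 is zero in both profiles of sample a but carried by sample b:
    # dataset scope keeps it for sample a, pair scope drops it.
    preds = {
        "a": _ko({"K1": 0.6, "K2": 0.4, "K3": 0.0}),
        "b": _ko({"K1": 0.2, "K2": 0.3, "K3": 0.5}),
    }
    metas = {
        "a": _ko({"K1": 0.7, "K2": 0.3, "K3": 0.0}),
        "b": _ko({"K1": 0.1, "K2": 0.4, "K3": 0.5}),
    }
    pair = evaluate_paired(preds, metas, exclusion_scope="pair")
    dataset = evaluate_paired(preds, metas, exclusion_scope="dataset")
    assert pair.dims_used["a"] == 2
    assert dataset.dims_used["a"] == 3
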