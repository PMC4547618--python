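"""Rank-correlation evaluation of paired predicted vs. shotgun KO profiles.

For each sample the predicted and metagenome-derived relative KO profiles are
aligned over their feature union, dimensions with zero mass in both are
excluded, and the Spearman coefficient (Pearson on mid-ranks, average ranks
for ties) is computed.  Two methods are compared with an exact two-sided
binomial sign test on per-sample coefficient differences (exact zeros are
dropped and counted).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (AmplifunError, NoNonzeroDifferencesError,
                     ZeroRankVarianceError)
from .profiles import AbundanceProfile, align_features

EXCLUSION_SCOPES = ("pair", "dataset")


def exclude_zero_dims(a: AbundanceProfile, b: AbundanceProfile
                      ) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    """Align two KO profiles and drop dimensions that are zero in both.

    Returns (retained KO ids, values of ``a``, values of ``b``).  Fewer than
    two retained dimensions leaves the correlation undefined and is an error.
    """
    if a.kind != "ko" or b.kind != "ko":
        raise AmplifunError("zero-dimension exclusion expects two ko profiles")
    ids, va, vb = align_features(a, b)
    keep = (va > 0) | (vb > 0)
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise AmplifunError(
            f"only {n_keep} KO dimension(s) retained after zero exclusion; "
            "correlation undefined")
    retained = tuple(i for i, k in zip(ids, keep) if k)
    return retained, va[keep], vb[keep]


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson on mid-ranks (ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise AmplifunError("spearman expects two equal-length vectors, n >= 2")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ZeroRankVarianceError(
            "constant vector: zero rank variance, correlation undefined")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    return min(max(rho, -1.0), 1.0)


@dataclass(frozen=True)
class SignTestResult:
    """Exact two-sided binomial sign test on paired differences."""

    p_value: float
    n_positive: int
    n_negative: int
    n_zero: int

    @property
    def n(self) -> int:
        return self.n_positive + self.n_negative


def sign_test(deltas: Sequence[float]) -> SignTestResult:
    """Exact sign test: X ~ Binomial(n, 1/2) over the nonzero differences.

    p = 2·min(P(X ≤ k), P(X ≥ k)) capped at 1, with k the number of positive
    differences among the n nonzero ones; exact zeros are dropped and counted.
    """
    d = np.asarray(deltas, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise AmplifunError("sign test expects a nonempty 1-D vector")
    nonzero = d[d != 0]
    n_zero = int(d.size - nonzero.size)
    if nonzero.size == 0:
        raise NoNonzeroDifferencesError(
            "all paired differences are exactly zero; sign test undefined")
    n = int(nonzero.size)
    k = int((nonzero > 0).sum())
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    p = 2.0 * min(lower, upper)
    return SignTestResult(p_value=float(min(p, 1.0)), n_positive=k,
                          n_negative=n - k, n_zero=n_zero)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-sample correlations, retained-dimension counts and comparison."""

    per_sample_rho: dict[str, float]
    dims_used: dict[str, int]
    median_rho: float
    competitor_rho: Optional[dict[str, float]] = None
    sign_test: Optional[SignTestResult] = None

    @property
    def sign_test_p(self) -> Optional[float]:
        return None if self.sign_test is None else self.sign_test.p_value

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.per_sample_rho))


def _dataset_support(pairs: Mapping[str, tuple[AbundanceProfile, AbundanceProfile]]
                     ) -> set[str]:
    support: set[str] = set()
    for pred, meta in pairs.values():
        for prof in (pred, meta):
            support.update(f for f, v in zip(prof.feature_ids, prof.values)
                           if v > 0)
    return support


def _pair_vectors(pred: AbundanceProfile, meta: AbundanceProfile,
                  scope: str, dataset_dims: Optional[set[str]]
                  ) -> tuple[int, np.ndarray, np.ndarray]:
    if scope == "pair":
        ids, va, vb = exclude_zero_dims(pred, meta)
        return len(ids), va, vb
    ids, va, vb = align_features(pred, meta)
    keep = np.array([i in dataset_dims for i in ids], dtype=bool)
    n_keep = int(keep.sum())
    if n_keep < 2:
        raise AmplifunError("fewer than 2 KO dimensions retained for dataset-"
                            "scope exclusion")
    return n_keep, va[keep], vb[keep]


def evaluate_paired(predictions: Mapping[str, AbundanceProfile],
                    metagenomes: Mapping[str, AbundanceProfile],
                    competitor: Optional[Mapping[str, AbundanceProfile]] = None,
                    exclusion_scope: str = "pair") -> EvaluationReport:
    """Evaluate predicted KO profiles against paired metagenome profiles.

    ``exclusion_scope`` controls the all-zero dimension exclusion: ``"pair"``
    drops, per sample, dimensions zero in both profiles of that pair
    (default); ``"dataset"`` drops dimensions zero in every profile of the
    whole collection, giving all samples a common dimension set.  With a
    ``competitor``, a sign test is run on per-sample (rho − rho_competitor).
    """
    if exclusion_scope not in EXCLUSION_SCOPES:
        raise AmplifunError(
            f"exclusion_scope must be one of {EXCLUSION_SCOPES}")
    shared = sorted(set(predictions) & set(metagenomes))
    if competitor is not None:
        shared = sorted(set(shared) & set(competitor))
    if not shared:
        raise AmplifunError("no shared sample identifiers to evaluate")

    dataset_dims = None
    comp_dataset_dims = None
    if exclusion_scope == "dataset":
        dataset_dims = _dataset_support(
            {s: (predictions[s], metagenomes[s]) for s in shared})
        if competitor is not None:
            comp_dataset_dims = _dataset_support(
                {s: (competitor[s], metagenomes[s]) for s in shared})

    per_sample: dict[str, float] = {}
    dims_used: dict[str, int] = {}
    comp_rho: dict[str, float] = {}
    for s in shared:
        n_dims, va, vb = _pair_vectors(predictions[s], metagenomes[s],
                                       exclusion_scope, dataset_dims)
        per_sample[s] = spearman(va, vb)
        dims_used[s] = n_dims
        if competitor is not None:
            _, ca, cb = _pair_vectors(competitor[s], metagenomes[s],
                                      exclusion_scope, comp_dataset_dims)
            comp_rho[s] = spearman(ca, cb)

    median = float(np.median([per_sample[s] for s in shared]))
    test = None
    if competitor is not None:
        deltas = [per_sample[s] - comp_rho[s] for s in shared]
        test = sign_test(deltas)
    return EvaluationReport(per_sample_rho=per_sample, dims_used=dims_used,
                            median_rho=median,
                            competitor_rho=comp_rho if competitor is not None else None,
                            sign_test=test)
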