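"""Labeled abundance profiles and the arithmetic every pipeline stage shares.

An :class:`AbundanceProfile` is a nonnegative vector over an ordered set of
feature identifiers.  The same container carries all three feature universes
the pipeline moves through: marker-reference assignments (``otu``), genome
abundances (``organism``) and functional abundances (``ko``).  Profiles hold
absolute counts until a stage explicitly normalizes them; the ``normalized``
flag asserts (and is validated to mean) that the values sum to one.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import EmptyProfileError, KindMismatchError, ProfileError

KINDS = ("otu", "organism", "ko")

#: absolute tolerance for "values sum to 1"
NORMALIZATION_ATOL = 1e-9


@dataclass(frozen=True)
class AbundanceProfile:
    """Nonnegative labeled abundance vector.

    Parameters
    ----------
    feature_ids :
        Ordered, duplicate-free identifiers (OTU / SILVA reference accessions,
        organism identifiers, or KO accessions depending on ``kind``).
    values :
        Nonnegative abundances, same length as ``feature_ids``.  Counts or
        relative fractions; unitless.
    kind :
        One of ``"otu"``, ``"organism"``, ``"ko"``.
    normalized :
        True iff the values sum to one within ``NORMALIZATION_ATOL``.
    """

    feature_ids: tuple[str, ...]
    values: np.ndarray
    kind: str
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.kind not in KINDS:
            raise ProfileError(f"unknown profile kind {self.kind!r}; expected one of {KINDS}")
        if len(self.feature_ids) != vals.shape[0] or vals.ndim != 1:
            raise ProfileError("feature_ids and values must be 1-D and of equal length")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ProfileError("duplicate feature identifiers in profile")
        if not np.all(np.isfinite(vals)):
            raise ProfileError("profile values must be finite")
        if np.any(vals < 0):
            raise ProfileError("profile values must be nonnegative")
        if self.normalized:
            total = float(vals.sum())
            if total == 0.0 or abs(total - 1.0) > NORMALIZATION_ATOL:
                raise ProfileError(
                    f"profile flagged normalized but values sum to {total!r}")
        vals.setflags(write=False)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float], kind: str,
                     normalized: bool = False) -> "AbundanceProfile":
        """Build a profile from a feature→value mapping, lexicographic order."""
        ids = tuple(sorted(mapping))
        vals = np.array([mapping[i] for i in ids], dtype=float)
        return cls(ids, vals, kind, normalized)

    # -- accessors ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return zip(self.feature_ids, self.values.tolist())

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def get(self, feature_id: str, default: float = 0.0) -> float:
        try:
            return float(self.values[self.feature_ids.index(feature_id)])
        except ValueError:
            return default

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature_ids, self.values.tolist()))

    def sorted(self) -> "AbundanceProfile":
        """Return the same profile with features in lexicographic order."""
        order = np.argsort(np.array(self.feature_ids, dtype=object))
        ids = tuple(self.feature_ids[i] for i in order)
        return AbundanceProfile(ids, self.values[order], self.kind, self.normalized)


class AlignedPair(NamedTuple):
    """Two profiles expressed over a shared, ordered feature union."""

    feature_ids: tuple[str, ...]
    a_values: np.ndarray
    b_values: np.ndarray


def normalize(profile: AbundanceProfile) -> AbundanceProfile:
    """Rescale to relative abundances summing to one.

    Preserves feature order and the ratios between features.  An all-zero
    profile cannot be normalized and raises :class:`EmptyProfileError` rather
    than returning NaNs.
    """
    total = profile.total
    if total <= 0.0:
        raise EmptyProfileError(
            f"cannot normalize an empty (all-zero) {profile.kind} profile")
    return AbundanceProfile(profile.feature_ids, profile.values / total,
                            profile.kind, normalized=True)


def align_features(a: AbundanceProfile, b: AbundanceProfile) -> AlignedPair:
    """Express two same-kind profiles over the union of their features.

    The union is ordered lexicographically; features absent from one profile
    are zero-filled, so each output vector sums to its input's total.
    """
    if a.kind != b.kind:
        raise KindMismatchError(
            f"cannot align a {a.kind!r} profile with a {b.kind!r} profile")
    union = tuple(sorted(set(a.feature_ids) | set(b.feature_ids)))
    index = {f: i for i, f in enumerate(union)}
    va = np.zeros(len(union))
    vb = np.zeros(len(union))
    for f, v in zip(a.feature_ids, a.values):
        va[index[f]] = v
    for f, v in zip(b.feature_ids, b.values):
        vb[index[f]] = v
    return AlignedPair(union, va, vb)
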