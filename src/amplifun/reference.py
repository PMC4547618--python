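"""Precomputed reference objects: association matrix, copy numbers, KO profiles.

The central primitive links each marker (SILVA-style) reference sequence to its
nearest sequenced genome by global 16S rRNA alignment identity, subject to a
minimum-identity threshold.  References whose best genome falls below the
threshold stay unmapped (an all-zero matrix column); exact ties split the
column weight uniformly, so every column of the association matrix is either
stochastic (sums to 1) or zero.

Identity is defined on the optimal global (end-to-end) alignment under a
linear gap model, by default match +1, mismatch −1, gap −1, as the fraction of
alignment columns that are identical matches.  When several alignments share
the optimal score their identities can differ; this module reports the
maximum identity over all optimal alignments.  That maximum has a closed
form: among alignments of fixed total score the identity is monotone in the
number of matches, so only the extremal match counts reachable along optimal
dynamic-programming paths are needed (a second DP pass).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit
from scipy import sparse

from .errors import AlphabetError, AmplifunError, MissingOrganismError

#: code assigned to N; scores as a mismatch against every symbol including N
_N_CODE = 4

_LUT = np.full(256, 255, dtype=np.uint8)
for _sym, _code in (("A", 0), ("C", 1), ("G", 2), ("T", 3), ("U", 3), ("N", 4)):
    _LUT[ord(_sym)] = _code
    _LUT[ord(_sym.lower())] = _code


@dataclass(frozen=True)
class Scoring:
    """Linear-gap global alignment scoring (integers).

    ``mismatch == 2 * gap`` is rejected: under that degenerate scoring a
    mismatch column and a gap pair are interchangeable, so the optimal score
    together with the match count no longer determines the alignment length
    and the maximum-identity closed form breaks down.
    """

    match: int = 1
    mismatch: int = -1
    gap: int = -1

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= self.match or self.gap >= self.match:
            raise ValueError("mismatch and gap scores must be below the match score")
        if self.mismatch == 2 * self.gap:
            raise ValueError(
                "degenerate scoring: mismatch == 2*gap makes identity ill-defined")


DEFAULT_SCORING = Scoring()


def encode_sequence(seq: str, context: str | None = None) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A=0,C=1,G=2,T=U=3,N=4)."""
    if not isinstance(seq, str) or len(seq) == 0:
        raise AmplifunError(f"empty sequence{' for ' + context if context else ''}")
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _LUT[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        raise AlphabetError(seq[int(bad[0])], context)
    return codes


@njit(cache=True)
def _nw_extremal_matches(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    F = np.empty((n + 1, m + 1), dtype=np.int64)
    F[0, 0] = 0
    for j in range(1, m + 1):
        F[0, j] = j * gap
    for i in range(1, n + 1):
        F[i, 0] = i * gap
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            sub = match if (ai == bj and ai != 4) else mismatch
            best = F[i - 1, j - 1] + sub
            t = F[i - 1, j] + gap
            if t > best:
                best = t
            t = F[i, j - 1] + gap
            if t > best:
                best = t
            F[i, j] = best
    # second pass: extremal match counts along score-optimal paths.  Every
    # cell has at least one tight incoming edge, so all cells are reachable.
    Mmax = np.zeros((n + 1, m + 1), dtype=np.int64)
    Mmin = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            is_match = 1 if (ai == bj and ai != 4) else 0
            sub = match if is_match == 1 else mismatch
            hi = np.int64(-1)
            lo = np.int64(1) << 60
            f = F[i, j]
            if f == F[i - 1, j - 1] + sub:
                c = Mmax[i - 1, j - 1] + is_match
                if c > hi:
                    hi = c
                c = Mmin[i - 1, j - 1] + is_match
                if c < lo:
                    lo = c
            if f == F[i - 1, j] + gap:
                if Mmax[i - 1, j] > hi:
                    hi = Mmax[i - 1, j]
                if Mmin[i - 1, j] < lo:
                    lo = Mmin[i - 1, j]
            if f == F[i, j - 1] + gap:
                if Mmax[i, j - 1] > hi:
                    hi = Mmax[i, j - 1]
                if Mmin[i, j - 1] < lo:
                    lo = Mmin[i, j - 1]
            Mmax[i, j] = hi
            Mmin[i, j] = lo
    return F[n, m], Mmin[n, m], Mmax[n, m]


def _identity_for_matches(matches: int, score: int, total_len: int,
                          scoring: Scoring) -> float:
    # For alignments of score s with M matches: X mismatches and G gap columns
    # satisfy s = match*M + mismatch*X + gap*G and G = total_len - 2M - 2X, so
    # X is determined, and columns L = total_len - M - X.
    denom = scoring.mismatch - 2 * scoring.gap
    num = score - scoring.gap * total_len - (scoring.match - 2 * scoring.gap) * matches
    x = num // denom
    cols = total_len - matches - x
    if cols <= 0:
        return 0.0
    return matches / cols


def pairwise_identity(seq_a: str, seq_b: str,
                      scoring: Scoring = DEFAULT_SCORING) -> float:
    """Global-alignment identity between two nucleotide sequences, in [0, 1].

    Identity = matches / alignment columns for the optimal global alignment
    under ``scoring``; with co-optimal alignments the maximum identity is
    returned.  ``U`` is treated as ``T``; ``N`` mismatches everything
    (including ``N``), keeping the identity a lower bound.  Symmetric in its
    arguments.
    """
    a = encode_sequence(seq_a, "first sequence")
    b = encode_sequence(seq_b, "second sequence")
    return _identity_from_codes(a, b, scoring)


def _identity_from_codes(a: np.ndarray, b: np.ndarray, scoring: Scoring) -> float:
    s, mmin, mmax = _nw_extremal_matches(a, b, scoring.match, scoring.mismatch,
                                         scoring.gap)
    total_len = int(a.shape[0] + b.shape[0])
    ident = max(_identity_for_matches(int(mmin), int(s), total_len, scoring),
                _identity_for_matches(int(mmax), int(s), total_len, scoring))
    # rational M/L in [0,1]; clip only guards float round-off
    return min(max(ident, 0.0), 1.0)


# --------------------------------------------------------------------------
# reference-side containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentityScore:
    reference_id: str
    organism_id: str
    identity: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise AmplifunError(f"identity {self.identity} outside [0, 1]")


@dataclass(frozen=True)
class AssociationMatrix:
    """Sparse organisms×references linear map from marker space to genomes.

    Every column sums to exactly 1 (reference mapped) or exactly 0 (no genome
    at or above the build threshold).
    """

    organism_ids: tuple[str, ...]
    reference_ids: tuple[str, ...]
    weights: sparse.csc_matrix
    min_identity: float

    def __post_init__(self):
        object.__setattr__(self, "organism_ids", tuple(self.organism_ids))
        object.__setattr__(self, "reference_ids", tuple(self.reference_ids))
        w = sparse.csc_matrix(self.weights)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.organism_ids), len(self.reference_ids)):
            raise AmplifunError("association matrix shape does not match labels")
        if w.nnz and w.data.min() < 0:
            raise AmplifunError("association weights must be nonnegative")
        sums = np.asarray(w.sum(axis=0)).ravel()
        ok = (sums == 0.0) | (sums == 1.0)
        if not bool(ok.all()):
            bad = self.reference_ids[int(np.nonzero(~ok)[0][0])]
            raise AmplifunError(
                f"association column {bad!r} sums to neither 0 nor 1")
        if not 0.0 < self.min_identity <= 1.0:
            raise AmplifunError("min_identity must lie in (0, 1]")

    @property
    def column_sums(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=0)).ravel()

    @property
    def mapped_references(self) -> tuple[str, ...]:
        sums = self.column_sums
        return tuple(r for r, s in zip(self.reference_ids, sums) if s > 0)

    def column(self, reference_id: str) -> dict[str, float]:
        j = self.reference_ids.index(reference_id)
        col = self.weights.getcol(j).tocoo()
        return {self.organism_ids[i]: float(v) for i, v in zip(col.row, col.data)}


@dataclass(frozen=True)
class CopyNumberTable:
    """Per-genome 16S rRNA gene copy counts (positive integers)."""

    organism_ids: tuple[str, ...]
    copy_numbers: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "organism_ids", tuple(self.organism_ids))
        cn = np.asarray(self.copy_numbers, dtype=np.int64)
        object.__setattr__(self, "copy_numbers", cn)
        if cn.ndim != 1 or cn.shape[0] != len(self.organism_ids):
            raise AmplifunError("copy_numbers must be 1-D, one per organism")
        if len(set(self.organism_ids)) != len(self.organism_ids):
            raise AmplifunError("duplicate organism ids in copy-number table")
        if cn.size and cn.min() < 1:
            bad = self.organism_ids[int(np.argmin(cn))]
            raise AmplifunError(f"copy number for {bad!r} must be >= 1")
        cn.setflags(write=False)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "CopyNumberTable":
        ids = tuple(sorted(mapping))
        return cls(ids, np.array([mapping[i] for i in ids], dtype=np.int64))

    def get(self, organism_id: str) -> int:
        return int(self.copy_numbers[self.organism_ids.index(organism_id)])

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.organism_ids, self.copy_numbers.tolist()))


@dataclass(frozen=True)
class ReferenceProfileSet:
    """Relative KO profile per genome; each row sums to one."""

    organism_ids: tuple[str, ...]
    ko_ids: tuple[str, ...]
    profiles: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "organism_ids", tuple(self.organism_ids))
        object.__setattr__(self, "ko_ids", tuple(self.ko_ids))
        p = np.asarray(self.profiles, dtype=float)
        object.__setattr__(self, "profiles", p)
        if p.shape != (len(self.organism_ids), len(self.ko_ids)):
            raise AmplifunError("profile matrix shape does not match labels")
        if p.size and p.min() < 0:
            raise AmplifunError("reference profiles must be nonnegative")
        sums = p.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise AmplifunError(
                f"reference profile row for {self.organism_ids[int(bad[0])]!r} "
                f"sums to {sums[int(bad[0])]!r}, not 1")
        p.setflags(write=False)

    def row(self, organism_id: str) -> np.ndarray:
        return self.profiles[self.organism_ids.index(organism_id)]


@dataclass(frozen=True)
class ReferenceDatabase:
    """Bundle of the precomputed objects the predictor consumes."""

    marker_sequences: dict[str, str]
    genome_marker_sequences: dict[str, tuple[str, ...]]
    association: AssociationMatrix
    copy_numbers: CopyNumberTable
    reference_profiles: ReferenceProfileSet
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        orgs = self.association.organism_ids
        if orgs != self.copy_numbers.organism_ids or \
                orgs != self.reference_profiles.organism_ids:
            raise MissingOrganismError(
                "organism identifiers disagree between association matrix, "
                "copy-number table and reference profiles")
        missing = [r for r in self.association.reference_ids
                   if r not in self.marker_sequences]
        if missing:
            raise AmplifunError(
                f"association references missing from marker sequences: {missing}")

    @property
    def organism_ids(self) -> tuple[str, ...]:
        return self.association.organism_ids


# --------------------------------------------------------------------------
# builders
# --------------------------------------------------------------------------

def _as_copies(value) -> tuple[str, ...]:
    if isinstance(value, str):
        return (value,)
    return tuple(value)


def build_association_matrix(marker_sequences: Mapping[str, str],
                             genome_marker_sequences: Mapping[str, object],
                             min_identity: float = 0.97,
                             scoring: Scoring = DEFAULT_SCORING,
                             tie_tolerance: float = 1e-12) -> AssociationMatrix:
    """Nearest-neighbor matching of marker references to genome 16S sequences.

    For each reference the genomes at or above ``min_identity`` are collected;
    among those the exact-maximum set (ties within ``tie_tolerance``) shares
    the column weight uniformly.  Genomes with multiple 16S copies score as
    the maximum identity over their copies.  Fully deterministic.
    """
    if not marker_sequences or not genome_marker_sequences:
        raise AmplifunError("marker and genome sequence sets must be nonempty")
    if not 0.0 < min_identity <= 1.0:
        raise AmplifunError(f"min_identity must lie in (0, 1], got {min_identity}")
    organisms = tuple(genome_marker_sequences)
    references = tuple(marker_sequences)
    genome_codes = [
        [encode_sequence(s, f"genome {org!r}") for s in _as_copies(genome_marker_sequences[org])]
        for org in organisms
    ]
    for org, codes in zip(organisms, genome_codes):
        if not codes:
            raise AmplifunError(f"genome {org!r} has no 16S sequence")

    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for j, ref in enumerate(references):
        ref_codes = encode_sequence(marker_sequences[ref], f"reference {ref!r}")
        idents = np.array([
            max(_identity_from_codes(ref_codes, g, scoring) for g in codes)
            for codes in genome_codes
        ])
        eligible = idents >= min_identity
        if not eligible.any():
            continue
        best = idents[eligible].max()
        tied = np.nonzero(eligible & (idents >= best - tie_tolerance))[0]
        w = np.full(tied.size, 1.0 / tied.size)
        w[-1] = 1.0 - float(w[:-1].sum())  # force exact column sum of 1
        for i, wi in zip(tied.tolist(), w.tolist()):
            rows.append(i)
            cols.append(j)
            data.append(wi)
    weights = sparse.csc_matrix((data, (rows, cols)),
                                shape=(len(organisms), len(references)))
    return AssociationMatrix(organisms, references, weights, min_identity)


def build_reference_profiles(
        ko_count_tables: Mapping[str, Mapping[str, float]]) -> ReferenceProfileSet:
    """Turn per-organism KO counts into relative reference profiles.

    The KO universe is the union of all KOs observed, zero-filled;
    organisms with no positive count are rejected by name.
    """
    if not ko_count_tables:
        raise AmplifunError("ko_count_tables must be nonempty")
    organisms = tuple(ko_count_tables)
    empty = [org for org in organisms
             if not any(v > 0 for v in ko_count_tables[org].values())]
    if empty:
        raise AmplifunError(
            f"organisms with no positive KO count: {sorted(empty)}")
    ko_ids = tuple(sorted({k for t in ko_count_tables.values() for k in t}))
    index = {k: i for i, k in enumerate(ko_ids)}
    mat = np.zeros((len(organisms), len(ko_ids)))
    for r, org in enumerate(organisms):
        for k, v in ko_count_tables[org].items():
            if v < 0:
                raise AmplifunError(f"negative KO count for {org!r}/{k!r}")
            mat[r, index[k]] = v
        mat[r] /= mat[r].sum()
    return ReferenceProfileSet(organisms, ko_ids, mat)


def _digest(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


def assemble_database(marker_sequences: Mapping[str, str],
                      genome_marker_sequences: Mapping[str, object],
                      ko_count_tables: Mapping[str, Mapping[str, float]],
                      copy_numbers: Mapping[str, int],
                      min_identity: float = 0.97,
                      scoring: Scoring = DEFAULT_SCORING) -> ReferenceDatabase:
    """Build a full :class:`ReferenceDatabase` from plain in-memory inputs.

    Organism identifier sets must agree across the genome-side inputs; the
    database uses lexicographic organism order so serialization is
    deterministic.  Metadata records the threshold, scoring and input digests.
    """
    genome_seqs = {org: _as_copies(v) for org, v in genome_marker_sequences.items()}
    sets = {
        "genome 16S sequences": set(genome_seqs),
        "KO count tables": set(ko_count_tables),
        "copy numbers": set(copy_numbers),
    }
    universe = set.union(*sets.values())
    problems = []
    for name, present in sets.items():
        missing = sorted(universe - present)
        if missing:
            problems.append(f"missing from {name}: {missing}")
    if problems:
        raise MissingOrganismError("; ".join(problems),
                                   organisms=sorted(universe))
    organisms = sorted(universe)
    association = build_association_matrix(
        dict(sorted(marker_sequences.items())),
        {org: genome_seqs[org] for org in organisms},
        min_identity=min_identity, scoring=scoring)
    profiles = build_reference_profiles(
        {org: dict(ko_count_tables[org]) for org in organisms})
    copies = CopyNumberTable(tuple(organisms),
                             np.array([copy_numbers[o] for o in organisms],
                                      dtype=np.int64))
    metadata = {
        "min_identity": repr(float(min_identity)),
        "scoring": f"match={scoring.match},mismatch={scoring.mismatch},gap={scoring.gap}",
        "marker_digest": _digest(dict(marker_sequences)),
        "genome_digest": _digest({k: list(v) for k, v in genome_seqs.items()}),
        "ko_digest": _digest({k: dict(v) for k, v in ko_count_tables.items()}),
        "copy_digest": _digest(dict(copy_numbers)),
    }
    return ReferenceDatabase(dict(marker_sequences), genome_seqs, association,
                             copies, profiles, metadata)
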