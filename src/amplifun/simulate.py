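"""Synthetic reference databases and paired 16S/metagenome samples.

The generator emulates the correspondence structure the predictor relies on:
each mock genome carries a 16S-like sequence; its marker-database reference is
that sequence with point substitutions at a configurable per-site rate
(mimicking intra-species divergence between a genome's rRNA and its database
representative); extra references with no genome relative emulate the large
fraction of marker-database diversity absent from genome databases.  Paired
samples consist of a multinomially sampled 16S read profile — deliberately
biased by 16S copy number, so the copy-number correction stage is exercised —
and an exactly computed shotgun-side KO profile, optionally perturbed by
multiplicative log-normal noise.

All generation is a pure, seed-deterministic function of the spec.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import io as io_formats
from .errors import AmplifunError
from .profiles import AbundanceProfile, normalize
from .reference import ReferenceDatabase, Scoring, assemble_database

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a mock reference world.

    Defaults model a small but realistic amplicon setting: full-length-ish
    500 nt marker regions, 1% divergence between a genome's 16S and its
    database reference (well above the conventional 97% species radius),
    1–5 rRNA operon copies, and genomes drawing ~30 KO functions from a
    universe of 150 so that genomes overlap functionally, as real KO cores do.
    """

    n_organisms: int = 10
    n_extra_silva_refs: int = 3
    seq_length: int = 500
    mutation_rate: float = 0.01
    n_kos_per_organism: int = 30
    copy_number_range: tuple[int, int] = (1, 5)
    seed: int = 0
    ko_universe_size: int = 150

    def __post_init__(self):
        if min(self.n_organisms, self.seq_length, self.n_kos_per_organism) < 1:
            raise AmplifunError("fixture counts must be >= 1")
        if self.n_extra_silva_refs < 0:
            raise AmplifunError("n_extra_silva_refs must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise AmplifunError("mutation_rate must lie in [0, 1]")
        lo, hi = self.copy_number_range
        if lo < 1 or hi < lo:
            raise AmplifunError("copy_number_range must be 1 <= lo <= hi")
        if self.ko_universe_size < self.n_kos_per_organism:
            raise AmplifunError(
                "ko_universe_size must be >= n_kos_per_organism")


@dataclass(frozen=True)
class ReferenceFixture:
    """Mock reference inputs plus the ground truth used to generate them."""

    spec: FixtureSpec
    marker_sequences: dict[str, str]
    genome_marker_sequences: dict[str, tuple[str, ...]]
    ko_counts: dict[str, dict[str, int]]
    copy_numbers: dict[str, int]
    #: reference id → organism id (None for decoy references)
    true_mapping: dict[str, Optional[str]]

    @property
    def organism_ids(self) -> tuple[str, ...]:
        return tuple(self.genome_marker_sequences)

    @property
    def reference_for_organism(self) -> dict[str, str]:
        return {org: ref for ref, org in self.true_mapping.items()
                if org is not None}

    def build_database(self, min_identity: float = 0.97,
                       scoring: Scoring = Scoring()) -> ReferenceDatabase:
        return assemble_database(self.marker_sequences,
                                 self.genome_marker_sequences,
                                 self.ko_counts, self.copy_numbers,
                                 min_identity=min_identity, scoring=scoring)

    def write(self, directory) -> Path:
        """Write the fixture in the tool's external input formats."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        io_formats.write_fasta(self.marker_sequences,
                               directory / "marker_refs.fasta")
        io_formats.write_genome_markers(self.genome_marker_sequences,
                                        directory / "genome_16s.fasta")
        io_formats.write_ko_counts(self.ko_counts, directory / "ko_counts.tsv")
        from .reference import CopyNumberTable
        io_formats.write_copy_numbers(
            CopyNumberTable.from_mapping(self.copy_numbers),
            directory / "copy_numbers.tsv")
        with (directory / "ground_truth.tsv").open("w") as fh:
            fh.write("reference_id\torganism_id\n")
            for ref in sorted(self.true_mapping):
                org = self.true_mapping[ref]
                fh.write(f"{ref}\t{org if org is not None else '-'}\n")
        return directory


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = np.array(list(seq))
    hits = rng.random(chars.size) < rate
    for i in np.nonzero(hits)[0]:
        others = [c for c in "ACGT" if c != chars[i]]
        chars[i] = others[rng.integers(len(others))]
    return "".join(chars)


def generate_reference_fixture(spec: FixtureSpec) -> ReferenceFixture:
    """Generate mock reference inputs with known reference→organism truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_organisms
    organisms = [f"org{i + 1:03d}" for i in range(n)]
    genome_seqs: dict[str, tuple[str, ...]] = {}
    markers: dict[str, str] = {}
    truth: dict[str, Optional[str]] = {}
    for i, org in enumerate(organisms):
        genome = _random_sequence(rng, spec.seq_length)
        genome_seqs[org] = (genome,)
        ref = f"SLV{i + 1:04d}"
        markers[ref] = _mutate(rng, genome, spec.mutation_rate)
        truth[ref] = org
    for j in range(spec.n_extra_silva_refs):
        ref = f"SLVX{j + 1:03d}"
        markers[ref] = _random_sequence(rng, spec.seq_length)
        truth[ref] = None
    ko_universe = [f"K{i + 1:05d}" for i in range(spec.ko_universe_size)]
    ko_counts: dict[str, dict[str, int]] = {}
    for org in organisms:
        chosen = rng.choice(spec.ko_universe_size, size=spec.n_kos_per_organism,
                            replace=False)
        counts = rng.integers(1, 50, size=spec.n_kos_per_organism)
        ko_counts[org] = {ko_universe[int(i)]: int(c)
                          for i, c in zip(chosen, counts)}
    lo, hi = spec.copy_number_range
    copies = {org: int(rng.integers(lo, hi + 1)) for org in organisms}
    return ReferenceFixture(spec=spec, marker_sequences=markers,
                            genome_marker_sequences=genome_seqs,
                            ko_counts=ko_counts, copy_numbers=copies,
                            true_mapping=truth)


def true_ko_profile(fixture: ReferenceFixture,
                    mixing_weights: Mapping[str, float]) -> AbundanceProfile:
    """Exact shotgun-side KO profile: convex combination of genome KO rows."""
    acc: dict[str, float] = {}
    for org, w in mixing_weights.items():
        counts = fixture.ko_counts[org]
        total = sum(counts.values())
        for ko, c in counts.items():
            acc[ko] = acc.get(ko, 0.0) + w * c / total
    return normalize(AbundanceProfile.from_mapping(acc, "ko"))


def generate_paired_sample(fixture: ReferenceFixture,
                           mixing_weights: Mapping[str, float],
                           n_reads: int = 10_000,
                           noise_rate: float = 0.0,
                           seed: int = 0,
                           exact: bool = False
                           ) -> tuple[AbundanceProfile, AbundanceProfile]:
    """Simulate one paired 16S / shotgun-metagenome sample.

    The 16S side distributes ``n_reads`` over the organisms' reference
    sequences with probability proportional to mixing weight × 16S copy
    number (the copy-number bias the correction stage must undo), drawn
    multinomially (or taken as exact expected counts with ``exact=True``).
    The metagenome side is the exact convex combination of the genomes'
    relative KO profiles, perturbed — when ``noise_rate > 0`` — by i.i.d.
    multiplicative log-normal factors with log-sd ``noise_rate`` and
    renormalized.

    Returns ``(otu_profile, true_metagenome_ko_profile)``.
    """
    if n_reads < 1:
        raise AmplifunError("n_reads must be >= 1")
    if noise_rate < 0:
        raise AmplifunError("noise_rate must be >= 0")
    organisms = list(mixing_weights)
    unknown = [o for o in organisms if o not in fixture.genome_marker_sequences]
    if unknown:
        raise AmplifunError(f"mixing weights name unknown organisms: {unknown}")
    w = np.array([mixing_weights[o] for o in organisms], dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise AmplifunError("mixing weights must be a distribution summing to 1")
    rng = np.random.default_rng(seed)
    ref_of = fixture.reference_for_organism
    copies = np.array([fixture.copy_numbers[o] for o in organisms], dtype=float)
    p = w * copies
    p = p / p.sum()
    if exact:
        counts = n_reads * p
    else:
        counts = rng.multinomial(n_reads, p).astype(float)
    refs = tuple(ref_of[o] for o in organisms)
    otu_profile = AbundanceProfile(refs, counts, "otu")

    truth = true_ko_profile(fixture, mixing_weights)
    if noise_rate > 0:
        factors = rng.lognormal(mean=0.0, sigma=noise_rate,
                                size=len(truth.feature_ids))
        truth = normalize(AbundanceProfile(truth.feature_ids,
                                           truth.values * factors, "ko"))
    return otu_profile, truth


def random_mixing_weights(fixture: ReferenceFixture, seed: int,
                          concentration: float = 5.0) -> dict[str, float]:
    """Dirichlet community composition over the fixture's organisms.

    Concentration 5 keeps every organism comfortably present, emulating a
    moderately even community.
    """
    rng = np.random.default_rng(seed)
    orgs = fixture.organism_ids
    w = rng.dirichlet(np.full(len(orgs), concentration))
    w = w / w.sum()
    return dict(zip(orgs, w.tolist()))


def recovery_benchmark(seeds: Iterable[int] = range(1, 11),
                       mutation_rate: float = 0.01,
                       min_identity: float = 0.97,
                       n_reads: int = 10_000,
                       noise_rates: Sequence[float] = (0.0,),
                       base_spec: Optional[FixtureSpec] = None
                       ) -> dict[float, list[float]]:
    """Per-seed Spearman between predicted and true KO profiles.

    For each seed a fresh mock reference world and one paired sample are
    generated; the full three-step prediction runs against the built
    database and is compared to the shotgun-side truth (zero dimensions
    excluded).  Returns ``{noise_rate: [rho per seed]}``; the same 16S sample
    is reused across noise rates (noise only perturbs the metagenome side),
    so rows are directly comparable.
    """
    from .evaluation import exclude_zero_dims, spearman
    from .predictor import predict

    spec0 = base_spec if base_spec is not None else FixtureSpec()
    results: dict[float, list[float]] = {float(nr): [] for nr in noise_rates}
    for seed in seeds:
        spec = replace(spec0, seed=int(seed), mutation_rate=mutation_rate)
        fixture = generate_reference_fixture(spec)
        db = fixture.build_database(min_identity=min_identity)
        weights = random_mixing_weights(fixture, seed=int(seed) + 10_000)
        for nr in noise_rates:
            otu, truth = generate_paired_sample(
                fixture, weights, n_reads=n_reads, noise_rate=float(nr),
                seed=int(seed) + 20_000)
            result = predict(otu, db)
            _, va, vb = exclude_zero_dims(result.ko_profile, truth)
            results[float(nr)].append(spearman(va, vb))
    return results
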