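"""Three-step functional prediction from a marker-gene community profile.

Given a community profile over SILVA-style reference sequences, prediction
proceeds:

1. linear transformation to a genome (organism) profile via the precomputed
   association matrix, dropping and reporting the mass on unmapped
   references, then renormalizing;
2. division by each genome's 16S rRNA copy number (apparent 16S abundance →
   approximate cell abundance), then renormalizing;
3. convex combination of the genomes' relative KO reference profiles with the
   normalized organism abundances.

Dropped (unmapped) mass is reported, never silently redistributed: the
coverage report carries the fraction of input mass that informed the
prediction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import (AmplifunError, MissingCopyNumberError, NoMappedOtusError,
                     ProfileError)
from .profiles import AbundanceProfile, normalize
from .reference import (AssociationMatrix, CopyNumberTable, ReferenceDatabase,
                        ReferenceProfileSet, _digest)


@dataclass(frozen=True)
class PredictionResult:
    """Predicted KO profile plus coverage diagnostics."""

    ko_profile: AbundanceProfile
    organism_profile: AbundanceProfile
    fraction_otus_unmapped: float
    inputs_digest: str = ""

    def __post_init__(self):
        if self.ko_profile.kind != "ko" or not self.ko_profile.normalized:
            raise ProfileError("ko_profile must be a normalized ko profile")
        if not 0.0 <= self.fraction_otus_unmapped <= 1.0:
            raise AmplifunError("fraction_otus_unmapped outside [0, 1]")


@dataclass(frozen=True)
class CoverageReport:
    """How much of the input signal reached the prediction."""

    fraction_otus_mapped: float
    fraction_otus_unmapped: float
    classified_read_fraction: Optional[float] = None
    overall_fraction: Optional[float] = None

    def as_dict(self) -> dict[str, float]:
        d = {
            "fraction_otus_mapped": self.fraction_otus_mapped,
            "fraction_otus_unmapped": self.fraction_otus_unmapped,
        }
        if self.classified_read_fraction is not None:
            d["classified_read_fraction"] = self.classified_read_fraction
            d["overall_fraction"] = self.overall_fraction
        return d


def transform_to_organism_profile(
        otu_profile: AbundanceProfile,
        association: AssociationMatrix) -> tuple[AbundanceProfile, float]:
    """Map marker-reference abundances to genome abundances (step 1).

    Input features absent from the matrix, or mapping to an all-zero column,
    contribute to the unmapped fraction.  Returns the renormalized organism
    profile together with that fraction.
    """
    if otu_profile.kind != "otu":
        raise ProfileError(f"expected an otu profile, got {otu_profile.kind!r}")
    input_mass = otu_profile.total
    if input_mass <= 0:
        raise NoMappedOtusError("input profile carries no mass")
    ref_index = {r: j for j, r in enumerate(association.reference_ids)}
    x = np.zeros(len(association.reference_ids))
    for f, v in zip(otu_profile.feature_ids, otu_profile.values):
        j = ref_index.get(f)
        if j is not None:
            x[j] += v
    organism_vec = association.weights @ x
    mapped_mass = float(organism_vec.sum())
    fraction_unmapped = (input_mass - mapped_mass) / input_mass
    if -1e-12 < fraction_unmapped < 0.0:  # float round-off in the matvec
        fraction_unmapped = 0.0
    if mapped_mass <= 0:
        raise NoMappedOtusError()
    profile = normalize(AbundanceProfile(association.organism_ids, organism_vec,
                                         "organism"))
    return profile, float(fraction_unmapped)


def normalize_by_copy_number(organism_profile: AbundanceProfile,
                             copy_numbers: CopyNumberTable,
                             assume_missing_copy_number_one: bool = False
                             ) -> AbundanceProfile:
    """Correct apparent 16S abundances for gene copy number (step 2).

    Every organism with positive abundance must have a copy number; a missing
    entry is an error by default (``assume_missing_copy_number_one`` opts into
    a silent default of 1).
    """
    if organism_profile.kind != "organism":
        raise ProfileError(
            f"expected an organism profile, got {organism_profile.kind!r}")
    table = copy_numbers.as_dict()
    missing = [f for f, v in zip(organism_profile.feature_ids,
                                 organism_profile.values)
               if v > 0 and f not in table]
    if missing and not assume_missing_copy_number_one:
        raise MissingCopyNumberError(
            f"no 16S copy number for abundant organisms: {missing}",
            organisms=missing)
    divisors = np.array([table.get(f, 1) for f in organism_profile.feature_ids],
                        dtype=float)
    return normalize(AbundanceProfile(organism_profile.feature_ids,
                                      organism_profile.values / divisors,
                                      "organism"))


def predict_functional_profile(normalized_organisms: AbundanceProfile,
                               reference_profiles: ReferenceProfileSet
                               ) -> AbundanceProfile:
    """Convex combination of genome KO reference rows (step 3)."""
    if normalized_organisms.kind != "organism":
        raise ProfileError("expected an organism profile")
    if abs(normalized_organisms.total - 1.0) > 1e-9:
        raise ProfileError("organism profile must be normalized before step 3")
    known = set(reference_profiles.organism_ids)
    missing = [f for f, v in zip(normalized_organisms.feature_ids,
                                 normalized_organisms.values)
               if v > 0 and f not in known]
    if missing:
        raise MissingOrganismProfileError(missing)
    ko_vec = np.zeros(len(reference_profiles.ko_ids))
    for f, v in zip(normalized_organisms.feature_ids, normalized_organisms.values):
        if v > 0:
            ko_vec += v * reference_profiles.row(f)
    return AbundanceProfile(reference_profiles.ko_ids, ko_vec, "ko",
                            normalized=True)


class MissingOrganismProfileError(AmplifunError):
    def __init__(self, organisms):
        self.organisms = tuple(organisms)
        super().__init__(
            f"abundant organisms lack a KO reference profile: {list(organisms)}")


def predict(otu_profile: AbundanceProfile, database: ReferenceDatabase,
            assume_missing_copy_number_one: bool = False) -> PredictionResult:
    """Run the full three-step prediction against a reference database."""
    organisms, fraction_unmapped = transform_to_organism_profile(
        otu_profile, database.association)
    corrected = normalize_by_copy_number(
        organisms, database.copy_numbers,
        assume_missing_copy_number_one=assume_missing_copy_number_one)
    ko = predict_functional_profile(corrected, database.reference_profiles)
    digest = _digest({
        "profile": {f: v for f, v in otu_profile},
        "db": database.metadata,
    })
    return PredictionResult(ko_profile=ko, organism_profile=corrected,
                            fraction_otus_unmapped=fraction_unmapped,
                            inputs_digest=digest)


def coverage_report(prediction: PredictionResult,
                    classified_read_fraction: Optional[float] = None
                    ) -> CoverageReport:
    """Summarize how much raw signal informed the prediction.

    ``classified_read_fraction`` is the upstream fraction of raw reads the
    16S pipeline classified; when given, the overall fraction of raw reads
    behind the prediction is its product with the mapped-OTU fraction.  When
    omitted it is reported as absent, never guessed.
    """
    mapped = 1.0 - prediction.fraction_otus_unmapped
    overall = None
    if classified_read_fraction is not None:
        if not 0.0 <= classified_read_fraction <= 1.0:
            raise AmplifunError("classified_read_fraction outside [0, 1]")
        overall = mapped * classified_read_fraction
    return CoverageReport(fraction_otus_mapped=mapped,
                          fraction_otus_unmapped=prediction.fraction_otus_unmapped,
                          classified_read_fraction=classified_read_fraction,
                          overall_fraction=overall)
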