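"""The three-step prediction pipeline and its coverage accounting."""
import numpy as np
import pytest
from scipy import sparse

from amplifun import (AbundanceProfile, AssociationMatrix, CopyNumberTable,
                      ReferenceProfileSet, coverage_report,
                      normalize_by_copy_number, predict,
                      predict_functional_profile,
                      transform_to_organism_profile)
from amplifun.errors import (MissingCopyNumberError, NoMappedOtusError,
                             ProfileError)


def _matrix(organisms, references, columns):
    """columns: reference -> {organism: weight}"""
    rows, cols, data = [], [], []
    for j, r in enumerate(references):
        for org, w in columns.get(r, {}).items():
            rows.append(organisms.index(org))
            cols.append(j)
            data.append(w)
    weights = sparse.csc_matrix((data, (rows, cols)),
                                shape=(len(organisms), len(references)))
    return AssociationMatrix(tuple(organisms), tuple(references), weights, 0.97)


def test_identity_association_relabels_profile():
    mat = _matrix(["gA", "gB"], ["r1", "r2"],
                  {"r1": {"gA": 1.0}, "r2": {"gB": 1.0}})
    profile = AbundanceProfile(("r1", "r2"), (30.0, 70.0), "otu")
    organisms, unmapped = transform_to_organism_profile(profile, mat)
    assert unmapped == 0.0
    assert organisms.as_dict() == {"gA": 0.3, "gB": 0.7}
    assert organisms.normalized


def test_split_column_divides_mass():
    mat = _matrix(["gX", "gY"], ["r1"], {"r1": {"gX": 0.5, "gY": 0.5}})
    profile = AbundanceProfile(("r1",), (100.0,), "otu")
    organisms, unmapped = transform_to_organism_profile(profile, mat)
    assert unmapped == 0.0
    assert organisms.as_dict() == {"gX": 0.5, "gY": 0.5}


def test_unmapped_mass_reported_exactly():
    mat = _matrix(["gA"], ["r1", "r2"], {"r1": {"gA": 1.0}})  # r2 all-zero
    profile = AbundanceProfile(("r1", "r2"), (80.0, 20.0), "otu")
    organisms, unmapped = transform_to_organism_profile(profile, mat)
    assert unmapped == 0.2
    assert organisms.as_dict() == {"gA": 1.0}


def test_absent_reference_counts_as_unmapped():
    mat = _matrix(["gA"], ["r1"], {"r1": {"gA": 1.0}})
    profile = AbundanceProfile(("r1", "r_unknown"), (60.0, 40.0), "otu")
    _, unmapped = transform_to_organism_profile(profile, mat)
    assert unmapped == 0.4


def test_fully_unmapped_profile_raises():
    mat = _matrix(["gA"], ["r1", "r2"], {"r1": {"gA": 1.0}})
    profile = AbundanceProfile(("r2",), (10.0,), "otu")
    with pytest.raises(NoMappedOtusError) as err:
        transform_to_organism_profile(profile, mat)
    assert err.value.fraction_unmapped == 1.0


def test_copy_number_correction_worked_value():
    profile = AbundanceProfile(("X", "Y"), (0.5, 0.5), "organism",
                               normalized=True)
    table = CopyNumberTable.from_mapping({"X": 1, "Y": 4})
    out = normalize_by_copy_number(profile, table)
    assert out.as_dict() == {"X": 0.8, "Y": 0.2}


def test_uniform_copy_numbers_leave_profile_unchanged():
    profile = AbundanceProfile(("X", "Y", "Z"), (0.2, 0.3, 0.5), "organism",
                               normalized=True)
    table = CopyNumberTable.from_mapping({"X": 3, "Y": 3, "Z": 3})
    out = normalize_by_copy_number(profile, table)
    np.testing.assert_allclose(out.values, profile.values, atol=1e-15)


def test_single_organism_always_normalizes_to_one():
    profile = AbundanceProfile(("X",), (0.4,), "organism")
    table = CopyNumberTable.from_mapping({"X": 7})
    assert normalize_by_copy_number(profile, table).as_dict() == {"X": 1.0}


def test_missing_copy_number_is_an_error_unless_opted_out():
    profile = AbundanceProfile(("X", "Y"), (0.5, 0.5), "organism",
                               normalized=True)
    table = CopyNumberTable.from_mapping({"X": 2})
    with pytest.raises(MissingCopyNumberError, match="Y"):
        normalize_by_copy_number(profile, table)
    out = normalize_by_copy_number(profile, table,
                                   assume_missing_copy_number_one=True)
    # X: 0.5/2, Y: 0.5/1 -> renormalized (1/3, 2/3)
    np.testing.assert_allclose(list(out.as_dict().values()), [1 / 3, 2 / 3])


def test_functional_profile_is_convex_combination():
    profs = ReferenceProfileSet(("X", "Y"), ("K00001", "K00002"),
                                np.array([[1.0, 0.0], [0.0, 1.0]]))
    mix = AbundanceProfile(("X", "Y"), (0.8, 0.2), "organism", normalized=True)
    out = predict_functional_profile(mix, profs)
    assert out.as_dict() == {"K00001": 0.8, "K00002": 0.2}
    assert out.normalized


def test_pure_culture_recovers_reference_row(ten_org_db, ten_org_fixture):
    ref_of = ten_org_fixture.reference_for_organism
    for org in ten_org_db.organism_ids:
        profile = AbundanceProfile((ref_of[org],), (1234.0,), "otu")
        result = predict(profile, ten_org_db)
        assert result.fraction_otus_unmapped == 0.0
        expected = ten_org_db.reference_profiles.row(org)
        np.testing.assert_allclose(result.ko_profile.values, expected,
                                   rtol=0, atol=1e-12)


def test_prediction_linear_in_raw_counts(ten_org_db, ten_org_fixture):
    """With full mapping and unit copy numbers, blending raw-count profiles
    blends the organism-stage outputs with the same proportions."""
    from amplifun import CopyNumberTable, ReferenceDatabase
    ref_of = ten_org_fixture.reference_for_organism
    orgs = ten_org_db.organism_ids
    unit = CopyNumberTable(orgs, np.ones(len(orgs), dtype=np.int64))
    db = ReferenceDatabase(ten_org_db.marker_sequences,
                           ten_org_db.genome_marker_sequences,
                           ten_org_db.association, unit,
                           ten_org_db.reference_profiles,
                           ten_org_db.metadata)
    p = AbundanceProfile((ref_of[orgs[0]], ref_of[orgs[1]]), (300.0, 100.0),
                         "otu")
    q = AbundanceProfile((ref_of[orgs[2]],), (400.0,), "otu")
    blend = AbundanceProfile(
        (ref_of[orgs[0]], ref_of[orgs[1]], ref_of[orgs[2]]),
        (300.0, 100.0, 400.0), "otu")
    ko_p = predict(p, db).ko_profile
    ko_q = predict(q, db).ko_profile
    ko_blend = predict(blend, db).ko_profile
    np.testing.assert_allclose(ko_blend.values,
                               0.5 * ko_p.values + 0.5 * ko_q.values,
                               atol=1e-12)


def test_mass_conserved_through_stages(ten_org_db, ten_org_fixture):
    ref_of = ten_org_fixture.reference_for_organism
    orgs = ten_org_db.organism_ids
    profile = AbundanceProfile(
        (ref_of[orgs[0]], ref_of[orgs[1]], "unknown_ref"),
        (50.0, 30.0, 20.0), "otu")
    result = predict(profile, ten_org_db)
    assert result.fraction_otus_unmapped == pytest.approx(0.2, abs=1e-12)
    assert result.organism_profile.total == pytest.approx(1.0, abs=1e-9)
    assert result.ko_profile.total == pytest.approx(1.0, abs=1e-9)


def test_coverage_report_values():
    from amplifun.predictor import PredictionResult
    ko = AbundanceProfile(("K00001", "K00002"), (0.5, 0.5), "ko",
                          normalized=True)
    org = AbundanceProfile(("X",), (1.0,), "organism", normalized=True)
    pred = PredictionResult(ko, org, fraction_otus_unmapped=0.2)
    rep = coverage_report(pred, classified_read_fraction=0.9)
    assert rep.fraction_otus_mapped == pytest.approx(0.8)
    assert rep.overall_fraction == pytest.approx(0.72)
    rep2 = coverage_report(PredictionResult(ko, org, 0.0))
    assert rep2.fraction_otus_mapped == 1.0
    assert rep2.classified_read_fraction is None
    assert rep2.overall_fraction is None


def test_wrong_profile_kind_rejected(three_org_db):
    ko = AbundanceProfile(("K00001",), (1.0,), "ko", normalized=True)
    with pytest.raises(ProfileError):
        transform_to_organism_profile(ko, three_org_db.association)
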