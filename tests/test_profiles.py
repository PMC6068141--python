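import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phifba.profiles import (
    CRITICAL_POINTS,
    ActivityRecord,
    HomologyTable,
    PHProfile,
    ProfileError,
    activity_at,
    aggregate_point,
    build_profiles,
    cross_validate,
    discretize_activity,
    fit_point_regressors,
    impute_profile,
    ph_optimum,
    read_profiles,
    transfer_from_homologs,
    write_profiles,
)

import pandas as pd


def make_profile(enzyme_id, values, source="experimental"):
    prof = PHProfile(enzyme_id=enzyme_id)
    for name, v in zip(CRITICAL_POINTS, values):
        if v is not None:
            prof.set_point(name, v, source)
    return prof


EXAMPLE = (6.0, 6.5, 7.0, 7.6, 8.0, 8.6)


def rec(enzyme, ph, act, kind="range"):
    return ActivityRecord(enzyme_id=enzyme, ec="1.1.1.1", taxon="t", ph=ph,
                          activity_pct=act, record_kind=kind)


# ---------------------------------------------------------------------------
# Binning and aggregation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "activity, level",
    [(60, 50), (10, 0), (100, 100), (0, 0), (25, 0), (25.0001, 50),
     (75, 50), (75.0001, 100), (50, 50), (76, 100)],
)
def test_discretize_bins_quarters_into_levels(activity, level):
    assert discretize_activity(activity) == level


@pytest.mark.parametrize("bad", [-1, 100.5, 1e6])
def test_discretize_rejects_out_of_range(bad):
    with pytest.raises(ProfileError):
        discretize_activity(bad)


def test_aggregate_point_is_the_median():
    assert aggregate_point([6.5]) == 6.5
    assert aggregate_point([6.0, 7.0, 8.0]) == 7.0
    assert aggregate_point([6.0, 7.0]) == 6.5
    with pytest.raises(ProfileError):
        aggregate_point([])


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def test_build_profiles_one_record_per_point():
    records = [rec("e", 6.0, 0), rec("e", 6.5, 50), rec("e", 7.0, 100, "optimum"),
               rec("e", 7.6, 100, "optimum"), rec("e", 8.0, 50), rec("e", 8.6, 0)]
    prof = build_profiles(records)["e"]
    assert [prof.point(p) for p in CRITICAL_POINTS] == list(EXAMPLE)
    assert prof.is_complete and prof.is_ordered and not prof.ordering_violated


def test_build_profiles_optimum_plateau_min_max_split():
    records = [rec("e", 7.0, 100, "optimum"), rec("e", 7.4, 100, "optimum")]
    prof = build_profiles(records)["e"]
    assert prof.A100 == 7.0 and prof.B100 == 7.4
    assert prof.missing == ("A0", "A50", "B50", "B0")


def test_build_profiles_degenerate_single_optimum():
    prof = build_profiles([rec("e", 7.2, 100, "optimum")])["e"]
    assert prof.A100 == prof.B100 == 7.2


def test_build_profiles_median_aggregation_within_point():
    records = [rec("e", 7.2, 100, "optimum"),
               rec("e", 6.0, 50), rec("e", 6.2, 50), rec("e", 6.7, 50)]
    prof = build_profiles(records)["e"]
    assert prof.A50 == 6.2  # median of the acidic-side half-activity records


def test_build_profiles_flags_ordering_violation():
    # a 0%-activity record *inside* the optimum plateau flank
    records = [rec("e", 7.0, 100, "optimum"), rec("e", 7.6, 100, "optimum"),
               rec("e", 7.2, 0)]
    prof = build_profiles(records)["e"]
    assert prof.ordering_violated


# ---------------------------------------------------------------------------
# Homolog transfer
# ---------------------------------------------------------------------------

def hom_table(query, hits):
    rows = [{"query_id": query, "hit_id": h, "rank": i + 1, "score": 100.0 - i}
            for i, h in enumerate(hits)]
    return HomologyTable(pd.DataFrame(rows))


def test_transfer_fills_missing_point_with_hit_median():
    db = {f"h{i}": make_profile(f"h{i}", (6.0, a50, 7.0, 7.5, 8.0, 8.5))
          for i, a50 in enumerate([6.2, 6.4, 6.9])}
    prof = make_profile("q", (6.0, None, 7.0, 7.5, 8.0, 8.5))
    out = transfer_from_homologs(prof, hom_table("q", ["h0", "h1", "h2"]), db, k=3)
    assert out.A50 == 6.4
    assert out.source_per_point["A50"] == "homolog"


def test_transfer_leaves_complete_profile_unchanged():
    prof = make_profile("q", EXAMPLE)
    out = transfer_from_homologs(prof, hom_table("q", ["h0"]), {}, k=5)
    assert out.points == prof.points


def test_transfer_with_empty_table_is_identity():
    prof = make_profile("q", (6.0, None, 7.0, 7.5, 8.0, 8.5))
    table = HomologyTable(pd.DataFrame(columns=["query_id", "hit_id", "rank", "score"]))
    assert transfer_from_homologs(prof, table, {}).missing == ("A50",)


def test_homology_table_rejects_bad_ranks():
    rows = pd.DataFrame([
        {"query_id": "q", "hit_id": "a", "rank": 1, "score": 1.0},
        {"query_id": "q", "hit_id": "b", "rank": 3, "score": 0.5},
    ])
    with pytest.raises(ProfileError):
        HomologyTable(rows)


# ---------------------------------------------------------------------------
# Regression imputation
# ---------------------------------------------------------------------------

def linear_training(n=40, seed=0, a50_offset=0.5):
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n):
        center = float(rng.uniform(6.5, 7.8))
        width = float(rng.uniform(0.1, 0.5))
        a100, b100 = center - width / 2, center + width / 2
        vals = (a100 - a50_offset - 0.4, a100 - a50_offset, a100, b100,
                b100 + a50_offset, b100 + a50_offset + 0.4)
        out[f"t{i}"] = make_profile(f"t{i}", vals)
    return out


def test_regressor_recovers_exact_linear_relation():
    reg = fit_point_regressors(linear_training())
    prof = make_profile("q", (None, None, 7.1, 7.4, 7.9, 8.3))
    pred = reg.predict_point("A50", prof.points)
    assert pred == pytest.approx(7.1 - 0.5, abs=1e-9)


def test_regressor_on_identical_profiles_predicts_the_constant():
    db = {f"t{i}": make_profile(f"t{i}", EXAMPLE) for i in range(12)}
    reg = fit_point_regressors(db)
    pred = reg.predict_point("B0", {"A100": 7.0, "B100": 7.6})
    assert pred == pytest.approx(8.6, abs=1e-6)


def test_regressor_recovers_unit_slope_from_noisy_data():
    rng = np.random.default_rng(1)
    db = {}
    for i in range(200):
        a100 = float(rng.uniform(6.5, 7.8))
        a0 = a100 - 1.0 + float(rng.normal(0, 0.05))
        db[f"t{i}"] = make_profile(f"t{i}", (a0, a100 - 0.5, a100, a100 + 0.3,
                                             a100 + 0.8, a100 + 1.2))
    reg = fit_point_regressors(db)
    intercept, coefs = reg.coefficients("A0", ("A100",))
    assert coefs[0] == pytest.approx(1.0, abs=0.05)


def test_regressors_require_enough_training():
    with pytest.raises(ProfileError):
        fit_point_regressors({f"t{i}": make_profile(f"t{i}", EXAMPLE) for i in range(5)})


def test_impute_fills_missing_point_and_sets_source():
    reg = fit_point_regressors(linear_training())
    prof = make_profile("q", (6.2, 6.6, 7.1, 7.4, 7.9, None))
    out = impute_profile(prof, regressors=reg)
    assert out.is_complete
    assert out.source_per_point["B0"] == "regressed"


def test_impute_is_identity_on_complete_profiles():
    reg = fit_point_regressors(linear_training())
    prof = make_profile("q", EXAMPLE)
    out = impute_profile(prof, regressors=reg)
    assert out.points == prof.points
    assert impute_profile(out, regressors=reg).points == out.points  # idempotent


def test_impute_from_plateau_only_recovers_flank_geometry():
    # training where half-activity points sit 0.7 pH units outside the plateau
    reg = fit_point_regressors(linear_training(a50_offset=0.7, seed=3))
    prof = make_profile("q", (None, None, 7.2, 7.2, None, None))
    out = impute_profile(prof, regressors=reg)
    assert out.A50 == pytest.approx(6.5, abs=0.01)
    assert out.B50 == pytest.approx(7.9, abs=0.01)


def test_impute_flags_ordering_violation_instead_of_clamping():
    # donors put the transferred half-activity point below the query's A0
    db = {f"h{i}": make_profile(f"h{i}", (6.0, 6.5, 7.0, 7.5, 8.0, 8.5))
          for i in range(3)}
    prof = make_profile("q", (7.0, None, 7.2, 7.5, 8.0, 8.4))
    out = impute_profile(prof, table=hom_table("q", list(db)), db=db)
    assert out.is_complete
    assert out.ordering_violated
    assert out.A50 < out.A0  # the violation is preserved, not repaired


def test_impute_rejects_empty_profile():
    with pytest.raises(ProfileError):
        impute_profile(PHProfile(enzyme_id="q"))


# ---------------------------------------------------------------------------
# Cross validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("protocol", ["kfold", "leave_species_out", "leave_ec_out"])
def test_cv_on_noise_free_linear_db_is_perfect(protocol):
    db = linear_training(n=60, seed=2)
    taxa = {k: f"sp{i % 6}" for i, k in enumerate(sorted(db))}
    ecs = {k: f"1.{i % 5}" for i, k in enumerate(sorted(db))}
    report = cross_validate(db, folds=5, protocol=protocol, seed=0, taxa=taxa, ecs=ecs)
    assert (report["pearson_r"] > 0.999999).all()
    assert (report["rmse"] < 1e-6).all()


def test_cv_constant_db_has_zero_rmse():
    db = {f"t{i}": make_profile(f"t{i}", EXAMPLE) for i in range(30)}
    report = cross_validate(db, folds=3, protocol="kfold", seed=0)
    assert (report["rmse"] < 1e-9).all()


def test_cv_noisy_linear_db_rmse_in_expected_band():
    rng = np.random.default_rng(0)
    db = {}
    for i in range(200):
        a100 = float(rng.uniform(6.5, 7.8))
        noise = rng.normal(0, 0.1, size=6)
        vals = np.array([a100 - 1.0, a100 - 0.5, a100, a100 + 0.3,
                         a100 + 0.8, a100 + 1.2]) + noise
        vals = np.sort(vals)
        db[f"t{i}"] = make_profile(f"t{i}", vals)
    report = cross_validate(db, folds=10, protocol="kfold", seed=0)
    assert ((report["rmse"] > 0.05) & (report["rmse"] < 0.2)).all()


def test_cv_rejects_too_few_profiles():
    db = {f"t{i}": make_profile(f"t{i}", EXAMPLE) for i in range(3)}
    with pytest.raises(ProfileError):
        cross_validate(db, folds=10, protocol="kfold")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def test_activity_at_nodes_and_midpoints():
    prof = make_profile("e", EXAMPLE)
    assert activity_at(prof, 7.0) == 100.0       # A100
    assert activity_at(prof, 6.75) == 75.0       # midpoint of A50-A100 segment
    assert activity_at(prof, 5.0) == 0.0         # below the acidic limit
    assert activity_at(prof, 6.5) == 50.0
    assert activity_at(prof, 8.0) == 50.0
    assert activity_at(prof, 7.3) == 100.0       # inside the plateau
    assert activity_at(prof, 9.0) == 0.0


def test_activity_at_degenerate_plateau():
    prof = make_profile("e", (6.5, 6.9, 7.2, 7.2, 7.5, 7.9))
    assert activity_at(prof, 7.2) == 100.0


def test_activity_at_requires_complete_profile():
    with pytest.raises(ProfileError):
        activity_at(make_profile("e", (6.0, None, 7.0, 7.5, 8.0, 8.5)), 7.0)


@settings(derandomize=True, max_examples=200)
@given(
    points=st.lists(st.floats(min_value=1.0, max_value=13.0), min_size=6, max_size=6),
    ph=st.floats(min_value=0.5, max_value=13.5),
)
def test_activity_at_shape_properties(points, ph):
    """Range, plateau value, flank monotonicity and the 0-outside rule."""
    vals = sorted(points)
    prof = make_profile("e", vals)
    a = activity_at(prof, ph)
    assert 0.0 <= a <= 100.0
    if vals[2] <= ph <= vals[3]:
        assert a == 100.0
    if ph < vals[0] or ph > vals[5]:
        assert a == 0.0
    # monotone: non-decreasing on the acidic flank, non-increasing on the basic
    eps = 1e-6
    if vals[0] < ph < ph + eps < vals[2]:
        assert activity_at(prof, ph + eps) >= a - 1e-9
    if vals[3] < ph < ph + eps < vals[5]:
        assert activity_at(prof, ph + eps) <= a + 1e-9


def test_ph_optimum_is_plateau_midpoint():
    assert ph_optimum(make_profile("e", (6.0, 6.5, 7.0, 8.0, 8.2, 8.6))) == 7.5
    assert ph_optimum(make_profile("e", (None, None, 7.2, 7.2, None, None))) == 7.2
    assert ph_optimum(make_profile("e", EXAMPLE)) == pytest.approx(7.3)
    with pytest.raises(ProfileError):
        ph_optimum(make_profile("e", (6.0, 6.5, None, None, 8.0, 8.6)))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def test_profile_tsv_round_trip(tmp_path):
    db = {
        "full": make_profile("full", EXAMPLE),
        "partial": make_profile("partial", (None, None, 7.2, 7.4, None, None)),
    }
    db["partial"].set_point("B50", 7.9, "homolog")
    path = tmp_path / "profiles.tsv"
    write_profiles(db, path)
    back = read_profiles(path)
    assert set(back) == set(db)
    for key in db:
        assert back[key].points == pytest.approx(db[key].points)
    assert back["partial"].source_per_point["B50"] == "homolog"
    assert back["partial"].missing == ("A0", "A50", "B0")
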