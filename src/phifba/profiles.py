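"""Six-point enzymatic pH-activity profiles.

An enzyme's pH dependence is summarised by six critical pH values at which
it shows 0%, 50% and 100% of its maximal activity, on the acidic (A) and
basic (B) flanks of the activity curve::

    activity
      100 |        A100______B100
       50 |      A50            B50
        0 | ___A0                  B0___
          +----------------------------- pH

Profiles are curated from tabular activity records (emulating BRENDA
"pH Optimum" / "pH Range" entries), completed by homolog transfer and
linear-regression imputation, and evaluated at arbitrary pH by piecewise
linear interpolation.  A complete, valid profile satisfies
``A0 <= A50 <= A100 <= B100 <= B50 <= B0``.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from sklearn.linear_model import LinearRegression

__all__ = [
    "CRITICAL_POINTS",
    "ActivityRecord",
    "PHProfile",
    "HomologyTable",
    "ProfileError",
    "discretize_activity",
    "aggregate_point",
    "build_profiles",
    "transfer_from_homologs",
    "PointRegressors",
    "fit_point_regressors",
    "impute_profile",
    "impute_db",
    "cross_validate",
    "activity_at",
    "ph_optimum",
    "read_records",
    "read_profiles",
    "write_profiles",
    "read_homology",
]

logger = logging.getLogger(__name__)

#: Canonical order of the six critical points (acidic flank then basic flank).
CRITICAL_POINTS = ("A0", "A50", "A100", "B100", "B50", "B0")

#: Activity level (percent of maximum) attached to each critical point.
POINT_LEVELS = {"A0": 0, "A50": 50, "A100": 100, "B100": 100, "B50": 50, "B0": 0}

#: Provenance flags, in decreasing order of trust.
SOURCES = ("experimental", "homolog", "regressed", "default")


class ProfileError(ValueError):
    """Raised for invalid activity records or unusable profiles."""


@dataclass(frozen=True)
class ActivityRecord:
    """One experimental measurement of relative enzyme activity at a pH.

    ``record_kind`` distinguishes "optimum" entries (reported pH of maximal
    activity) from "range" entries (activity at the edges of a reported pH
    range); both carry an explicit ``activity_pct`` in [0, 100].
    """

    enzyme_id: str
    ec: str
    taxon: str
    ph: float
    activity_pct: float
    record_kind: str = "range"

    def __post_init__(self) -> None:
        if not (0.0 <= self.activity_pct <= 100.0):
            raise ProfileError(
                f"activity_pct must be in [0, 100], got {self.activity_pct!r} "
                f"for enzyme {self.enzyme_id!r}"
            )
        if not (0.0 < self.ph < 14.0):
            raise ProfileError(
                f"ph must be in (0, 14), got {self.ph!r} for enzyme {self.enzyme_id!r}"
            )
        if self.record_kind not in ("optimum", "range"):
            raise ProfileError(f"unknown record_kind {self.record_kind!r}")


@dataclass
class PHProfile:
    """The six critical pH points of one enzyme, with per-point provenance.

    Missing points are ``None`` until imputation.  ``source_per_point`` maps
    each present point to one of :data:`SOURCES`.
    """

    enzyme_id: str
    A0: float | None = None
    A50: float | None = None
    A100: float | None = None
    B100: float | None = None
    B50: float | None = None
    B0: float | None = None
    source_per_point: dict = field(default_factory=dict)
    ordering_violated: bool = False

    def point(self, name: str) -> float | None:
        if name not in CRITICAL_POINTS:
            raise KeyError(name)
        return getattr(self, name)

    def set_point(self, name: str, value: float, source: str) -> None:
        if name not in CRITICAL_POINTS:
            raise KeyError(name)
        if source not in SOURCES:
            raise ValueError(f"unknown source {source!r}")
        setattr(self, name, float(value))
        self.source_per_point[name] = source

    @property
    def points(self) -> dict:
        """Present points as an ordered name -> pH mapping."""
        return {
            p: getattr(self, p) for p in CRITICAL_POINTS if getattr(self, p) is not None
        }

    @property
    def missing(self) -> tuple:
        return tuple(p for p in CRITICAL_POINTS if getattr(self, p) is None)

    @property
    def is_complete(self) -> bool:
        return not self.missing

    @property
    def is_ordered(self) -> bool:
        """True when the present points respect the A0..B0 ordering."""
        vals = [getattr(self, p) for p in CRITICAL_POINTS if getattr(self, p) is not None]
        return all(a <= b for a, b in zip(vals, vals[1:]))

    def validate(self) -> None:
        """Reject incomplete or mis-ordered profiles."""
        if not self.is_complete:
            raise ProfileError(
                f"profile {self.enzyme_id!r} incomplete: missing {self.missing}"
            )
        if not self.is_ordered:
            raise ProfileError(
                f"profile {self.enzyme_id!r} violates A0<=A50<=A100<=B100<=B50<=B0: "
                f"{[getattr(self, p) for p in CRITICAL_POINTS]}"
            )

    def copy(self) -> "PHProfile":
        return replace(self, source_per_point=dict(self.source_per_point))


@dataclass
class HomologyTable:
    """Precomputed homology hits: ``query_id, hit_id, rank, score``.

    The table is the tabular output of an external profile-HMM search
    (e.g. jackhmmer); running the search is out of scope here.  Per query,
    ranks must be unique and start at 1 (rank 1 = closest homolog).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"query_id", "hit_id", "rank", "score"}
        if not required.issubset(self.frame.columns):
            raise ProfileError(
                f"homology table needs columns {sorted(required)}, "
                f"got {list(self.frame.columns)}"
            )
        for query, grp in self.frame.groupby("query_id"):
            ranks = sorted(grp["rank"].tolist())
            if ranks != list(range(1, len(ranks) + 1)):
                raise ProfileError(
                    f"ranks for query {query!r} must be unique and start at 1, "
                    f"got {ranks}"
                )

    def hits(self, query_id: str, k: int | None = None) -> list:
        """The ``k`` closest hit ids for ``query_id``, closest first."""
        grp = self.frame[self.frame["query_id"] == query_id].sort_values("rank")
        ids = grp["hit_id"].tolist()
        return ids if k is None else ids[:k]


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def discretize_activity(activity_pct: float) -> int:
    """Bin a relative activity into the 0 / 50 / 100% level of its record.

    Activities up to 25% are approximated to 0%, activities in (25, 75] to
    50%, and activities above 75% to 100%.  The interval edges are closed on
    the left bin ("up to 25%" is honoured inclusively), which makes the
    binning deterministic for the ambiguous boundary records.
    """
    if not (0.0 <= activity_pct <= 100.0):
        raise ProfileError(f"activity_pct must be in [0, 100], got {activity_pct!r}")
    if activity_pct in (25.0, 75.0):
        logger.debug("boundary activity %.6g binned into the lower level", activity_pct)
    if activity_pct <= 25.0:
        return 0
    if activity_pct <= 75.0:
        return 50
    return 100


def aggregate_point(values) -> float:
    """Median pH of the records contributing to one critical point.

    For even counts this is the mean of the two middle values.  An empty
    list signals that the critical point has no data.
    """
    values = list(values)
    if not values:
        raise ProfileError("no data for this critical point")
    return float(statistics.median(values))


def build_profiles(records) -> dict:
    """Curate activity records into (possibly incomplete) six-point profiles.

    Per enzyme, each record is binned with :func:`discretize_activity`.
    100%-level records define the optimum plateau: they are split at the
    midpoint of their span into an acidic and a basic group, and A100/B100
    take the per-group medians (a single record, or a one-sided group,
    gives a degenerate plateau A100 = B100).  0%- and 50%-level records are
    assigned to the acidic or basic flank by their position relative to the
    plateau midpoint (or to the median record pH when no 100%-level record
    exists), and each flank point takes the median of its contributing pH
    values.

    Profiles whose points violate the A0..B0 ordering are flagged via
    ``ordering_violated`` — never silently re-sorted.
    """
    by_enzyme: dict = {}
    for rec in records:
        by_enzyme.setdefault(rec.enzyme_id, []).append(rec)

    profiles: dict = {}
    for enzyme_id, recs in by_enzyme.items():
        levels: dict = {0: [], 50: [], 100: []}
        for rec in recs:
            levels[discretize_activity(rec.activity_pct)].append(rec.ph)

        prof = PHProfile(enzyme_id=enzyme_id)
        if levels[100]:
            split = (min(levels[100]) + max(levels[100])) / 2.0
            acid100 = [ph for ph in levels[100] if ph <= split]
            base100 = [ph for ph in levels[100] if ph > split]
            prof.set_point(
                "A100", aggregate_point(acid100 or base100), "experimental"
            )
            prof.set_point(
                "B100", aggregate_point(base100 or acid100), "experimental"
            )
            midpoint = (prof.A100 + prof.B100) / 2.0
        else:
            midpoint = aggregate_point([r.ph for r in recs])

        for level, (acid_name, base_name) in ((50, ("A50", "B50")), (0, ("A0", "B0"))):
            acid = [ph for ph in levels[level] if ph <= midpoint]
            base = [ph for ph in levels[level] if ph > midpoint]
            if acid:
                prof.set_point(acid_name, aggregate_point(acid), "experimental")
            if base:
                prof.set_point(base_name, aggregate_point(base), "experimental")

        if not prof.is_ordered:
            prof.ordering_violated = True
            logger.warning(
                "profile %s violates critical-point ordering after curation", enzyme_id
            )
        profiles[enzyme_id] = prof
    return profiles


# ---------------------------------------------------------------------------
# Imputation: homolog transfer, then regression
# ---------------------------------------------------------------------------

def transfer_from_homologs(
    profile: PHProfile,
    table: HomologyTable,
    db: dict,
    k: int = 5,
) -> PHProfile:
    """Fill missing critical points from the k closest homologs' profiles.

    Each missing point becomes the median of that point over the ``k``
    closest hits that report it.  Points no hit reports stay missing.
    The input profile is not modified.
    """
    out = profile.copy()
    if out.is_complete:
        return out
    hit_ids = table.hits(profile.enzyme_id, k=k)
    hit_profiles = [db[h] for h in hit_ids if h in db]
    for name in out.missing:
        donor_vals = [p.point(name) for p in hit_profiles if p.point(name) is not None]
        if donor_vals:
            out.set_point(name, aggregate_point(donor_vals), "homolog")
    return out


class PointRegressors:
    """Per-critical-point ordinary-least-squares predictors.

    For a target point the regressor is fit on whichever other points are
    available at prediction time ("listwise" feature patterns): one OLS model
    per (target, feature-subset) pair, fit lazily from the complete training
    profiles and cached.  The design is deliberately pluggable — any object
    with the same ``predict_point`` signature can replace it.
    """

    MIN_TRAINING = 10

    def __init__(self, training: dict | list):
        profs = list(training.values()) if isinstance(training, dict) else list(training)
        complete = [p for p in profs if p.is_complete and p.is_ordered]
        if len(complete) < self.MIN_TRAINING:
            raise ProfileError(
                f"need >= {self.MIN_TRAINING} complete training profiles, "
                f"got {len(complete)}"
            )
        self._matrix = np.array(
            [[p.point(name) for name in CRITICAL_POINTS] for p in complete]
        )
        self._cache: dict = {}

    def _fit(self, target: str, features: tuple) -> LinearRegression:
        key = (target, features)
        if key not in self._cache:
            ti = CRITICAL_POINTS.index(target)
            fi = [CRITICAL_POINTS.index(f) for f in features]
            X = self._matrix[:, fi]
            y = self._matrix[:, ti]
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) < X.shape[1] + 1:
                # Degenerate design (e.g. constant training columns): OLS
                # falls back to the least-norm solution, which still predicts
                # the constant; flag it for inspection rather than failing.
                logger.warning(
                    "rank-deficient regression design for %s given %s", target, features
                )
            self._cache[key] = LinearRegression().fit(X, y)
        return self._cache[key]

    def coefficients(self, target: str, features: tuple) -> tuple:
        """(intercept, coefs) of the OLS model for this feature pattern."""
        model = self._fit(target, tuple(features))
        return float(model.intercept_), np.asarray(model.coef_, dtype=float)

    def predict_point(self, target: str, available: dict) -> float:
        """Predict one critical point from the available points of a profile."""
        features = tuple(sorted(available, key=CRITICAL_POINTS.index))
        if not features:
            raise ProfileError("cannot regress a point from an empty profile")
        model = self._fit(target, features)
        x = np.array([[available[f] for f in features]])
        return float(model.predict(x)[0])


def fit_point_regressors(training) -> PointRegressors:
    """Fit the per-point OLS regressor set on complete training profiles."""
    return PointRegressors(training)


#: Imputation order: optimum-plateau points first (they anchor the flanks and
#: carry most experimental support), then the half-activity, then the limits.
IMPUTE_ORDER = ("A100", "B100", "A50", "B50", "A0", "B0")


def impute_profile(
    profile: PHProfile,
    table: HomologyTable | None = None,
    db: dict | None = None,
    regressors: PointRegressors | None = None,
    k: int = 5,
) -> PHProfile:
    """Complete a profile: homolog transfer first, then point regression.

    At least one point must be present (an all-missing enzyme is unusable).
    The completed profile must satisfy the critical-point ordering; a
    violating result is returned with ``ordering_violated`` set so callers
    can drop and report it (it is never clamped into order).  Complete
    profiles pass through unchanged, making the operation idempotent.
    """
    if not profile.points:
        raise ProfileError(f"profile {profile.enzyme_id!r} has no points to impute from")
    out = profile.copy()
    if table is not None and db is not None:
        out = transfer_from_homologs(out, table, db, k=k)
    if regressors is not None:
        for name in IMPUTE_ORDER:
            if out.point(name) is None:
                out.set_point(name, regressors.predict_point(name, out.points), "regressed")
    if out.is_complete:
        out.ordering_violated = not out.is_ordered
        if out.ordering_violated:
            logger.warning(
                "imputed profile %s violates critical-point ordering; "
                "flagged invalid", out.enzyme_id,
            )
    return out


def impute_db(
    db: dict,
    table: HomologyTable | None = None,
    regressors: PointRegressors | None = None,
    k: int = 5,
) -> tuple:
    """Impute every profile in a db; returns (complete_valid, dropped_ids)."""
    complete: dict = {}
    dropped: list = []
    for enzyme_id, prof in db.items():
        try:
            full = impute_profile(prof, table, db, regressors, k=k)
        except ProfileError:
            dropped.append(enzyme_id)
            continue
        if full.is_complete and not full.ordering_violated:
            complete[enzyme_id] = full
        else:
            dropped.append(enzyme_id)
    return complete, dropped


# ---------------------------------------------------------------------------
# Cross validation
# ---------------------------------------------------------------------------

def cross_validate(
    db,
    folds: int = 10,
    protocol: str = "kfold",
    seed: int = 0,
    taxa: dict | None = None,
    ecs: dict | None = None,
) -> pd.DataFrame:
    """Held-out prediction quality of the point regressors, per critical point.

    Three split protocols of increasing stringency are supported:

    - ``kfold``: seeded shuffle into ``folds`` folds;
    - ``leave_species_out``: folds are taxa (requires ``taxa``:
      enzyme_id -> taxon); every taxon's enzymes are held out together;
    - ``leave_ec_out``: folds are top-level EC classes (requires ``ecs``).

    For each held-out profile each point is hidden in turn and predicted
    from the remaining five by regressors fit on the training fold only.
    Returns a DataFrame indexed by critical point with columns
    ``pearson_r``, ``rmse`` and ``n``.
    """
    profs = {k: v for k, v in db.items() if v.is_complete and v.is_ordered}
    if protocol == "kfold":
        if len(profs) < folds:
            raise ProfileError(f"need >= {folds} complete profiles, got {len(profs)}")
        rng = np.random.default_rng(seed)
        ids = sorted(profs)
        order = rng.permutation(len(ids))
        groups = [[ids[i] for i in order[f::folds]] for f in range(folds)]
    elif protocol in ("leave_species_out", "leave_ec_out"):
        mapping = taxa if protocol == "leave_species_out" else ecs
        what = "taxa" if protocol == "leave_species_out" else "ecs"
        if mapping is None:
            raise ProfileError(f"protocol {protocol!r} requires the {what} mapping")
        by_group: dict = {}
        for enzyme_id in sorted(profs):
            by_group.setdefault(mapping.get(enzyme_id, "?"), []).append(enzyme_id)
        groups = [by_group[g] for g in sorted(by_group)]
        if len(groups) < 2:
            raise ProfileError("need >= 2 groups to cross-validate")
    else:
        raise ProfileError(f"unknown protocol {protocol!r}")

    truths: dict = {p: [] for p in CRITICAL_POINTS}
    preds: dict = {p: [] for p in CRITICAL_POINTS}
    for held_out in groups:
        train = {k: v for k, v in profs.items() if k not in held_out}
        if len(train) < PointRegressors.MIN_TRAINING:
            raise ProfileError("training folds too small for the point regressors")
        reg = PointRegressors(train)
        for enzyme_id in held_out:
            prof = profs[enzyme_id]
            for name in CRITICAL_POINTS:
                available = {p: v for p, v in prof.points.items() if p != name}
                truths[name].append(prof.point(name))
                preds[name].append(reg.predict_point(name, available))

    rows = []
    for name in CRITICAL_POINTS:
        t = np.asarray(truths[name])
        p = np.asarray(preds[name])
        resid = p - t
        rmse = float(np.sqrt(np.mean(resid**2)))
        if np.ptp(t) == 0 or np.ptp(p) == 0:
            # Degenerate (constant) columns: perfect iff residuals vanish.
            r = 1.0 if np.allclose(resid, 0) else float("nan")
        else:
            r = float(_scipy_stats.pearsonr(t, p).statistic)
        rows.append({"point": name, "pearson_r": r, "rmse": rmse, "n": len(t)})
    return pd.DataFrame(rows).set_index("point")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def activity_at(profile: PHProfile, ph: float) -> float:
    """Percent activity at a pH, linearly interpolated through the six points.

    The curve passes through (A0, 0), (A50, 50), (A100, 100), (B100, 100),
    (B50, 50), (B0, 0), is 0 outside [A0, B0], and is continuous everywhere;
    zero-width segments (coincident points) take the higher activity level.
    """
    profile.validate()
    xs = [profile.point(p) for p in CRITICAL_POINTS]
    ys = [float(POINT_LEVELS[p]) for p in CRITICAL_POINTS]
    if ph < xs[0] or ph > xs[-1]:
        return 0.0
    if xs[2] <= ph <= xs[3]:  # on the optimum plateau
        return 100.0
    best = 0.0
    for (x0, y0), (x1, y1) in zip(zip(xs, ys), zip(xs[1:], ys[1:])):
        if x0 <= ph <= x1:
            if x1 == x0:
                val = max(y0, y1)
            else:
                val = y0 + (y1 - y0) * (ph - x0) / (x1 - x0)
            best = max(best, val)
    return float(best)


def ph_optimum(profile: PHProfile) -> float:
    """The pH optimum, defined as the midpoint of the 100%-activity plateau."""
    if profile.A100 is None or profile.B100 is None:
        raise ProfileError(
            f"profile {profile.enzyme_id!r} lacks the optimum plateau (A100/B100)"
        )
    return (profile.A100 + profile.B100) / 2.0


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["enzyme_id", "ec", "taxon", "ph", "activity_pct", "record_kind"]
PROFILE_COLUMNS = (
    ["enzyme_id"]
    + list(CRITICAL_POINTS)
    + [f"src_{p}" for p in CRITICAL_POINTS]
)


def read_records(path) -> list:
    """Read activity records from a TSV with the canonical header."""
    frame = pd.read_csv(path, sep="\t")
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ProfileError(f"records file {path} lacks columns {sorted(missing)}")
    return [
        ActivityRecord(
            enzyme_id=str(row.enzyme_id),
            ec=str(row.ec),
            taxon=str(row.taxon),
            ph=float(row.ph),
            activity_pct=float(row.activity_pct),
            record_kind=str(row.record_kind),
        )
        for row in frame.itertuples(index=False)
    ]


def write_profiles(db: dict, path) -> None:
    """Write a profile db as TSV; missing points are encoded as ``NA``."""
    rows = []
    for enzyme_id in sorted(db):
        prof = db[enzyme_id]
        row: dict = {"enzyme_id": enzyme_id}
        for p in CRITICAL_POINTS:
            row[p] = prof.point(p)
            row[f"src_{p}"] = prof.source_per_point.get(p)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_profiles(path) -> dict:
    """Read a profile db written by :func:`write_profiles`."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    db: dict = {}
    for row in frame.itertuples(index=False):
        prof = PHProfile(enzyme_id=str(row.enzyme_id))
        for p in CRITICAL_POINTS:
            val = getattr(row, p)
            if val is not None and not (isinstance(val, float) and math.isnan(val)):
                src = getattr(row, f"src_{p}")
                if not isinstance(src, str):
                    src = "experimental"
                prof.set_point(p, float(val), src)
        prof.ordering_violated = not prof.is_ordered
        db[prof.enzyme_id] = prof
    return db


def read_homology(path) -> HomologyTable:
    """Read a homology table TSV (``query_id  hit_id  rank  score``)."""
    return HomologyTable(pd.read_csv(path, sep="\t"))
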