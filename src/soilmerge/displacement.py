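"""Transplant-displacement statistic from paired ASV abundances.

The question: after a whole-community transplant is merged into a resident
community, which resident taxa are permanently displaced (enriched or
depleted) relative to the non-merged control?

Procedure.  For each replicate pair and sampling day, transplant reads are
removed, both samples are subsampled without replacement to a common depth
D (default 100 000 reads), and ASVs detected in *both* samples are paired as
(x, y) = (log10 count in condition A, log10 count in condition B).  An
ordinary least-squares line y = b0 + b1*x is fitted to the pooled day-0
pairs — at the moment of merging the transplant cannot yet have acted, so
the day-0 residual dispersion sigma is the null scale of replicate plus
counting variation.  At every later day, a paired ASV whose residual
d = y - (b0 + b1*x) exceeds k*sigma in magnitude (k = 3, the two-sided
99.7% normal band) is called a displacement outlier: enriched if d > 0,
depleted if d < 0.  Summing |d| over all outliers of a replicate pair
across days gives a per-pair displacement magnitude, compared between the
merged-vs-control contrast and within-control contrasts (no merger, pure
replicate noise).

The baseline/outlier rule is exposed as the scikit-learn style estimator
:class:`BaselineOutlierDetector`; the module functions wrap it into the
paired-count workflow.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import tables

__all__ = [
    "DisplacementConfig",
    "ReplicatePair",
    "Comparison",
    "BaselineOutlierDetector",
    "build_comparison_pairs",
    "pair_common_asvs",
    "fit_baseline",
    "detect_outliers",
    "summed_outlier_distance",
    "outlier_phylum_profile",
    "run_displacement",
    "DisplacementResult",
]


@dataclass(frozen=True)
class DisplacementConfig:
    """Tunable knobs of the displacement analysis.

    k_sigma
        Threshold multiplier on the baseline residual dispersion; 3 gives
        the two-sided 99.7% normal band.
    depth
        Rarefaction depth in reads applied to every sample after transplant
        reads are removed.
    seed
        Seed for subsampling and the random between-condition replicate
        pairing.
    threshold_basis
        ``"residual_sd"`` (default): flag |d| > k * sigma.
        ``"prediction_se"``: use the x-dependent OLS standard error of
        prediction instead of the constant sigma.
    """

    k_sigma: float = 3.0
    depth: int = 100_000
    seed: int = 0
    threshold_basis: str = "residual_sd"

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.threshold_basis not in ("residual_sd", "prediction_se"):
            raise ValueError(f"unknown threshold_basis {self.threshold_basis!r}")


@dataclass(frozen=True)
class ReplicatePair:
    """One paired comparison: replicate of condition A vs replicate of B."""

    condition_a: str
    replicate_a: int
    condition_b: str
    replicate_b: int

    @property
    def label(self) -> str:
        return (
            f"{self.condition_a}.r{self.replicate_a}"
            f"~{self.condition_b}.r{self.replicate_b}"
        )


class BaselineOutlierDetector(OutlierMixin, BaseEstimator):
    """Regression-baseline outlier detector for paired log10 abundances.

    Fits an ordinary least-squares line y = intercept_ + slope_ * x on the
    null (day-0) pairs and flags later points whose residual magnitude
    exceeds ``k_sigma`` times the baseline residual standard deviation
    ``sigma_`` (computed with the n-2 OLS denominator).  Follows the
    scikit-learn outlier-detector convention: ``predict`` returns +1 for
    inliers and -1 for outliers, and ``decision_function`` is negative for
    outliers.

    Parameters
    ----------
    k_sigma : float, default 3.0
        Band half-width in units of the residual dispersion (3 = the
        two-sided 99.7% normal band).
    threshold_basis : {"residual_sd", "prediction_se"}
        Constant band (default) or the x-dependent OLS standard error of
        prediction.
    """

    def __init__(self, k_sigma: float = 3.0, threshold_basis: str = "residual_sd"):
        self.k_sigma = k_sigma
        self.threshold_basis = threshold_basis

    # X is an (n, 2) array of (x, y) pairs: this detector models the second
    # column as a linear response to the first.
    def fit(self, X, y=None) -> "BaselineOutlierDetector":
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.threshold_basis not in ("residual_sd", "prediction_se"):
            raise ValueError(f"unknown threshold_basis {self.threshold_basis!r}")
        X = check_array(X, ensure_min_samples=3, ensure_2d=True)
        if X.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (x, y) pairs")
        x, yv = X[:, 0], X[:, 1]
        if np.ptp(x) == 0:
            raise ValueError("zero variance in x; baseline regression undefined")
        fit = stats.linregress(x, yv)
        resid = yv - (fit.intercept + fit.slope * x)
        n = len(x)
        self.slope_ = float(fit.slope)
        self.intercept_ = float(fit.intercept)
        self.sigma_ = float(np.sqrt(np.sum(resid**2) / (n - 2)))
        self.n_points_ = n
        self.x_mean_ = float(np.mean(x))
        self.sxx_ = float(np.sum((x - self.x_mean_) ** 2))
        return self

    def residuals(self, X) -> np.ndarray:
        check_is_fitted(self, "sigma_")
        X = check_array(X, ensure_2d=True)
        return X[:, 1] - (self.intercept_ + self.slope_ * X[:, 0])

    def threshold(self, X) -> np.ndarray:
        """Band half-width at each point's x (constant for residual_sd)."""
        check_is_fitted(self, "sigma_")
        X = check_array(X, ensure_2d=True)
        if self.threshold_basis == "residual_sd":
            return np.full(len(X), self.k_sigma * self.sigma_)
        x = X[:, 0]
        se_pred = self.sigma_ * np.sqrt(
            1.0 + 1.0 / self.n_points_ + (x - self.x_mean_) ** 2 / self.sxx_
        )
        return self.k_sigma * se_pred

    def decision_function(self, X) -> np.ndarray:
        """Positive inside the band, negative for outliers."""
        return self.threshold(X) - np.abs(self.residuals(X))

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) < 0, -1, 1)


# ---------------------------------------------------------------------------
# pairing


def build_comparison_pairs(
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str | None = None,
    mode: str = "within",
    seed: int = 0,
) -> list[ReplicatePair]:
    """Replicate pairs for a within- or between-condition comparison.

    ``mode="within"``: all C(R, 2) unordered replicate pairs of one
    condition (6 pairs for R = 4).  ``mode="between"``: a seeded random
    bijection between the replicates of the two conditions (R pairs; 4 for
    R = 4), i.e. each replicate is used exactly once on each side.
    """
    def _reps(cond: str) -> list[int]:
        reps = sorted(metadata.loc[metadata["condition"] == cond, "replicate"].unique())
        if not reps:
            raise ValueError(f"condition {cond!r} absent from metadata")
        if len(reps) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        return reps

    if mode == "within":
        if group_b is not None and group_b != group_a:
            raise ValueError("within-mode comparisons use a single condition")
        reps = _reps(group_a)
        return [
            ReplicatePair(group_a, ra, group_a, rb)
            for ra, rb in itertools.combinations(reps, 2)
        ]
    if mode == "between":
        if group_b is None:
            raise ValueError("between-mode comparisons need two conditions")
        reps_a = _reps(group_a)
        reps_b = _reps(group_b)
        if len(reps_a) != len(reps_b):
            raise ValueError(
                f"between-mode pairing needs equal replicate counts "
                f"({len(reps_a)} vs {len(reps_b)})"
            )
        rng = np.random.default_rng(seed)
        shuffled = rng.permutation(reps_b)
        return [
            ReplicatePair(group_a, ra, group_b, int(rb))
            for ra, rb in zip(reps_a, shuffled)
        ]
    raise ValueError(f"mode must be 'within' or 'between', got {mode!r}")


def _sample_for(metadata: pd.DataFrame, condition: str, replicate: int, day: float) -> str:
    ids = tables.sample_ids_for(metadata, condition, replicate, day)
    if not ids:
        raise ValueError(f"no sample for ({condition!r}, replicate {replicate}, day {day})")
    return ids[0]


def pair_common_asvs(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    pair: ReplicatePair,
    day: float,
    exclude: Iterable[str] = (),
    config: DisplacementConfig | None = None,
) -> pd.DataFrame:
    """Paired log10 abundances of ASVs common to both samples of a pair.

    Transplant (excluded) ASVs are removed first, each sample is then
    rarefied to ``config.depth`` reads, and only ASVs with a nonzero count
    on *both* sides are retained.  Returns a frame with columns (asv_id,
    count_a, count_b, x, y) and pair/day recorded in ``attrs``.
    """
    config = config or DisplacementConfig()
    sid_a = _sample_for(metadata, pair.condition_a, pair.replicate_a, day)
    sid_b = _sample_for(metadata, pair.condition_b, pair.replicate_b, day)
    sub = counts.loc[[sid_a, sid_b]]
    exclude = set(exclude)
    if exclude:
        sub = sub.drop(columns=[c for c in sub.columns if c in exclude])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rare = tables.rarefy(sub, config.depth, seed=config.seed)
    lost = [s for s in (sid_a, sid_b) if s not in rare.index]
    if lost:
        raise ValueError(
            f"sample(s) {lost} hold fewer than {config.depth} reads after "
            "exclusion; cannot rarefy"
        )
    ca, cb = rare.loc[sid_a], rare.loc[sid_b]
    common = (ca >= 1) & (cb >= 1)
    if int(common.sum()) < 3:
        raise ValueError(
            f"only {int(common.sum())} common ASVs between {sid_a} and {sid_b}; "
            "need at least 3"
        )
    out = pd.DataFrame(
        {
            "asv_id": ca.index[common],
            "count_a": ca[common].to_numpy(),
            "count_b": cb[common].to_numpy(),
        }
    )
    out["x"] = np.log10(out["count_a"])
    out["y"] = np.log10(out["count_b"])
    out.attrs["pair"] = pair
    out.attrs["day"] = day
    return out


# ---------------------------------------------------------------------------
# baseline and outliers


def fit_baseline(pairs_t0: Sequence[pd.DataFrame] | pd.DataFrame) -> BaselineOutlierDetector:
    """OLS baseline pooled over all day-0 replicate pairs of a comparison."""
    if isinstance(pairs_t0, pd.DataFrame):
        pooled = pairs_t0
    else:
        pooled = pd.concat(list(pairs_t0), ignore_index=True)
    if len(pooled) < 3:
        raise ValueError(f"baseline needs >= 3 pooled points, got {len(pooled)}")
    return BaselineOutlierDetector().fit(pooled[["x", "y"]].to_numpy())


def detect_outliers(
    pairs: pd.DataFrame,
    model: BaselineOutlierDetector,
    config: DisplacementConfig | None = None,
) -> pd.DataFrame:
    """Flag paired ASVs outside the baseline band.

    Returns one record per outlier with the residual d (log10 units),
    direction (enriched when d > 0, i.e. higher in condition B), the log2
    fold change of rarefied counts, and the ASV's relative abundance in
    condition B at the rarefaction depth.  With a degenerate sigma = 0
    baseline every nonzero residual is flagged (a warning is emitted).
    """
    config = config or DisplacementConfig()
    X = pairs[["x", "y"]].to_numpy()
    resid = model.residuals(X)
    if model.sigma_ == 0:
        if np.any(resid != 0):
            warnings.warn(
                "baseline residual dispersion is 0; every nonzero residual "
                "is flagged as an outlier",
                stacklevel=2,
            )
        flagged = resid != 0
    else:
        thresh = config.k_sigma * (
            model.threshold(X) / model.k_sigma  # honour the model's basis
        )
        flagged = np.abs(resid) > thresh
    out = pairs.loc[flagged].copy()
    out["residual"] = resid[flagged]
    out["direction"] = np.where(out["residual"] > 0, "enriched", "depleted")
    out["log2_fold_change"] = np.log2(out["count_b"] / out["count_a"])
    out["rel_abundance_b"] = out["count_b"] / config.depth
    if "pair" in pairs.attrs:
        out["pair"] = pairs.attrs["pair"].label
    if "day" in pairs.attrs:
        out["day"] = pairs.attrs["day"]
    return out.reset_index(drop=True)


def summed_outlier_distance(
    outliers: pd.DataFrame,
    pair_index: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Total |residual| per (comparison, replicate pair), summed across days.

    ``outliers`` is a concatenation of :func:`detect_outliers` outputs with
    ``comparison`` and ``pair`` columns.  ``pair_index`` lists every
    (comparison, pair label) that was analysed so that pairs without any
    outlier report a distance of 0.  The per-comparison median of the
    per-pair sums is attached in ``attrs["medians"]``.
    """
    if len(outliers):
        sums = (
            outliers.assign(distance=outliers["residual"].abs())
            .groupby(["comparison", "pair"], as_index=False)["distance"]
            .sum()
        )
    else:
        sums = pd.DataFrame(columns=["comparison", "pair", "distance"])
    if pair_index is not None:
        full = pd.DataFrame(sorted(set(pair_index)), columns=["comparison", "pair"])
        sums = full.merge(sums, on=["comparison", "pair"], how="left").fillna(
            {"distance": 0.0}
        )
    sums["distance"] = sums["distance"].astype(float)
    sums.attrs["medians"] = sums.groupby("comparison")["distance"].median()
    return sums


def outlier_phylum_profile(
    outliers: pd.DataFrame,
    taxonomy: pd.DataFrame,
    rel: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    merged_condition: str | None = None,
) -> pd.DataFrame:
    """Phylum-level summary of outlier ASVs per day.

    Groups outlier records by (phylum, day) and reports the mean log2 fold
    change over replicate pairs, counts of enriched/depleted records, and
    the mean relative abundance of the outlier ASVs in the merged-community
    background (from ``rel`` restricted to ``merged_condition`` samples
    when provided, otherwise from the rarefied counts of condition B).
    """
    if not len(outliers):
        return pd.DataFrame(
            columns=[
                "phylum", "day", "mean_log2_fold_change", "n_outliers",
                "n_enriched", "n_depleted", "mean_rel_abundance",
            ]
        )
    missing = set(outliers["asv_id"]) - set(taxonomy.index)
    if missing:
        raise KeyError(f"no taxonomy for outlier ASV(s): {sorted(missing)[:5]}")
    df = outliers.copy()
    df["phylum"] = taxonomy.loc[df["asv_id"], "phylum"].to_numpy()
    if rel is not None:
        if metadata is not None and merged_condition is not None:
            ids = tables.sample_ids_for(metadata, condition=merged_condition)
            rel = rel.loc[rel.index.intersection(ids)]
        background = rel.mean(axis=0)
        df["rel_background"] = df["asv_id"].map(background).fillna(0.0)
    else:
        df["rel_background"] = df["rel_abundance_b"]
    out = (
        df.groupby(["phylum", "day"], as_index=False)
        .agg(
            mean_log2_fold_change=("log2_fold_change", "mean"),
            n_outliers=("asv_id", "size"),
            n_enriched=("direction", lambda d: int((d == "enriched").sum())),
            n_depleted=("direction", lambda d: int((d == "depleted").sum())),
            mean_rel_abundance=("rel_background", "mean"),
        )
    )
    return out


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass(frozen=True)
class Comparison:
    """A named comparison: e.g. merged vs control (between) or within-control."""

    name: str
    group_a: str
    group_b: str
    mode: str  # "between" or "within"


@dataclass
class DisplacementResult:
    points: pd.DataFrame
    baselines: dict[str, BaselineOutlierDetector]
    outliers: pd.DataFrame
    summary: pd.DataFrame
    config: DisplacementConfig = field(default_factory=DisplacementConfig)

    def baseline_params(self) -> dict[str, dict[str, float]]:
        return {
            name: {
                "slope": m.slope_,
                "intercept": m.intercept_,
                "sigma": m.sigma_,
                "n_points": m.n_points_,
            }
            for name, m in self.baselines.items()
        }


def run_displacement(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    comparisons: Sequence[Comparison],
    exclude: Iterable[str] = (),
    config: DisplacementConfig | None = None,
    days: Sequence[float] | None = None,
) -> DisplacementResult:
    """Full displacement analysis over a set of comparisons.

    For every comparison the replicate pairing is built once, the baseline
    is fitted on the pooled day-0 pairs, and outliers are called at every
    sampled day against that fixed day-0 line.
    """
    config = config or DisplacementConfig()
    exclude = frozenset(exclude)
    all_points, all_outliers = [], []
    baselines: dict[str, BaselineOutlierDetector] = {}
    pair_index: list[tuple[str, str]] = []
    for comp in comparisons:
        pairs = build_comparison_pairs(
            metadata, comp.group_a, comp.group_b, mode=comp.mode, seed=config.seed
        )
        conds = {comp.group_a, comp.group_b}
        comp_days = days
        if comp_days is None:
            comp_days = sorted(
                metadata.loc[metadata["condition"].isin(conds), "day"].unique()
            )
        if 0 not in comp_days:
            raise ValueError(
                f"comparison {comp.name!r} has no day-0 samples for the baseline"
            )
        paired: dict[tuple[str, float], pd.DataFrame] = {}
        for pair in pairs:
            pair_index.append((comp.name, pair.label))
            for day in comp_days:
                tbl = pair_common_asvs(counts, metadata, pair, day, exclude, config)
                tbl = tbl.assign(comparison=comp.name, pair=pair.label, day=day)
                tbl.attrs.update({"pair": pair, "day": day})
                paired[(pair.label, day)] = tbl
        t0 = [tbl for (lbl, day), tbl in paired.items() if day == 0]
        model = fit_baseline(t0)
        baselines[comp.name] = model
        for tbl in paired.values():
            all_points.append(tbl)
            out = detect_outliers(tbl, model, config)
            if len(out):
                out["comparison"] = comp.name
                all_outliers.append(out)
    points = pd.concat(all_points, ignore_index=True)
    outliers = (
        pd.concat(all_outliers, ignore_index=True)
        if all_outliers
        else pd.DataFrame(
            columns=list(points.columns)
            + ["residual", "direction", "log2_fold_change", "rel_abundance_b"]
        )
    )
    summary = summed_outlier_distance(outliers, pair_index)
    return DisplacementResult(
        points=points,
        baselines=baselines,
        outliers=outliers,
        summary=summary,
        config=config,
    )
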