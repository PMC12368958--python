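"""Interval-based demographic accounting of community growth and decline.

For each time interval (day_a, day_b) and community, the change of every
genus is Delta_a = mean_b(a) - mean_a(a) in cells g^-1 soil, where means are
taken over biological replicates at each endpoint.  Genera are then grouped
by whether they are common to the two communities being contrasted or
exclusive to one, and by whether they increase or decrease in each;
summing Delta_a within groups (split into its positive and negative parts)
quantifies how much each group contributes to overall community growth and
decline in that interval.  By construction the signed group contributions
sum exactly to the total community-size change.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_INTERVALS",
    "GROUP_LABELS",
    "interval_deltas",
    "presence_set",
    "classify_taxa_groups",
    "contribution_summary",
]

#: Default analysis intervals in days: early bloom, crash, late succession.
DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = ((0, 3), (3, 7), (7, 21))

GROUP_LABELS = (
    "common_increasing_both",
    "common_decreasing_both",
    "common_opposite_A_up",
    "common_opposite_B_up",
    "exclusive_A_increasing",
    "exclusive_A_decreasing",
    "exclusive_B_increasing",
    "exclusive_B_decreasing",
    "unchanged",
)


def interval_deltas(
    abs_table: pd.DataFrame,
    metadata: pd.DataFrame,
    community: str,
    intervals: Sequence[tuple[float, float]] = DEFAULT_INTERVALS,
) -> pd.DataFrame:
    """Per-taxon absolute-abundance changes over the given day intervals.

    ``abs_table`` is a sample x taxon absolute-abundance table (typically
    genus-aggregated); rows are matched to ``metadata`` and restricted to
    ``community``.  Replicate means are taken at each endpoint day.

    Returns a tidy frame with columns (taxon, day_a, day_b, community,
    delta).
    """
    meta = metadata.loc[metadata.index.intersection(abs_table.index)]
    meta = meta[meta["condition"] == community]
    if meta.empty:
        raise ValueError(f"no samples for community {community!r}")
    available = sorted(meta["day"].unique())
    day_means: dict[float, pd.Series] = {}
    records = []
    for day_a, day_b in intervals:
        if not day_a < day_b:
            raise ValueError(f"interval endpoints must be ordered: ({day_a}, {day_b})")
        for day in (day_a, day_b):
            if day not in available:
                raise ValueError(
                    f"day {day} not sampled for {community!r}; available: {available}"
                )
            if day not in day_means:
                ids = meta.index[meta["day"] == day]
                day_means[day] = abs_table.loc[ids].mean(axis=0)
        delta = day_means[day_b] - day_means[day_a]
        if not np.isfinite(delta.to_numpy()).all():
            raise ValueError(f"non-finite abundance change in interval ({day_a}, {day_b})")
        records.append(
            pd.DataFrame(
                {
                    "taxon": delta.index,
                    "day_a": day_a,
                    "day_b": day_b,
                    "community": community,
                    "delta": delta.to_numpy(),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def presence_set(
    counts: pd.DataFrame, metadata: pd.DataFrame, community: str
) -> set[str]:
    """Taxa detected (nonzero count) in any sample of ``community``."""
    meta = metadata.loc[metadata.index.intersection(counts.index)]
    ids = meta.index[meta["condition"] == community]
    if not len(ids):
        raise ValueError(f"no samples for community {community!r}")
    totals = counts.loc[ids].sum(axis=0)
    return set(totals.index[totals > 0])


def _sign_label(da: float, db: float) -> str:
    if da == 0 and db == 0:
        return "unchanged"
    # a zero delta counts as weak agreement with the other community's sign
    if da >= 0 and db >= 0:
        return "common_increasing_both"
    if da <= 0 and db <= 0:
        return "common_decreasing_both"
    return "common_opposite_A_up" if da > 0 else "common_opposite_B_up"


def classify_taxa_groups(
    deltas_a: pd.DataFrame,
    deltas_b: pd.DataFrame,
    presence_a: Iterable[str],
    presence_b: Iterable[str],
) -> pd.DataFrame:
    """Partition taxa into common/exclusive increasing/decreasing groups.

    ``deltas_a``/``deltas_b`` are :func:`interval_deltas` outputs for the
    two communities over the same intervals.  Presence sets are
    community-wide detection sets (a taxon is common when detected in both
    communities at any sampled timepoint).  Every (taxon, interval) receives
    exactly one label.
    """
    presence_a, presence_b = set(presence_a), set(presence_b)
    ia = {tuple(k) for k in deltas_a[["day_a", "day_b"]].drop_duplicates().to_numpy()}
    ib = {tuple(k) for k in deltas_b[["day_a", "day_b"]].drop_duplicates().to_numpy()}
    if ia != ib:
        raise ValueError(f"delta tables cover different intervals: {ia} vs {ib}")
    rows = []
    for (day_a, day_b) in sorted(ia):
        sub_a = deltas_a[(deltas_a["day_a"] == day_a) & (deltas_a["day_b"] == day_b)]
        sub_b = deltas_b[(deltas_b["day_a"] == day_a) & (deltas_b["day_b"] == day_b)]
        map_a = dict(zip(sub_a["taxon"], sub_a["delta"]))
        map_b = dict(zip(sub_b["taxon"], sub_b["delta"]))
        for taxon in sorted(set(map_a) | set(map_b)):
            in_a, in_b = taxon in presence_a, taxon in presence_b
            if not in_a and not in_b:
                raise ValueError(f"taxon {taxon!r} has deltas but is in neither presence set")
            da, db = map_a.get(taxon, 0.0), map_b.get(taxon, 0.0)
            if in_a and in_b:
                label = _sign_label(da, db)
            elif in_a:
                if da == 0:
                    label = "unchanged"
                else:
                    label = "exclusive_A_increasing" if da > 0 else "exclusive_A_decreasing"
            else:
                if db == 0:
                    label = "unchanged"
                else:
                    label = "exclusive_B_increasing" if db > 0 else "exclusive_B_decreasing"
            rows.append((taxon, day_a, day_b, label))
    return pd.DataFrame(rows, columns=["taxon", "day_a", "day_b", "group"])


def contribution_summary(
    deltas: pd.DataFrame, groups: pd.DataFrame | Mapping[str, str]
) -> pd.DataFrame:
    """Summed growth/decline contributions per taxa group and interval.

    ``groups`` is either the frame from :func:`classify_taxa_groups` or any
    taxon -> label mapping defining a partition (e.g. guild assignments).
    Per (interval, group): growth_sum = sum of positive deltas, decline_sum
    = sum of negative deltas, and the fractional shares of the interval's
    total growth and total decline.  ``total_change`` repeats the interval's
    net community-size change; summing (growth_sum + decline_sum) over
    groups recovers it exactly.
    """
    df = deltas.copy()
    if isinstance(groups, pd.DataFrame):
        df = df.merge(groups, on=["taxon", "day_a", "day_b"], how="left")
    else:
        df["group"] = df["taxon"].map(dict(groups))
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "taxon"].unique().tolist()
        raise ValueError(f"taxa without a group label: {missing[:5]}")
    df["growth"] = df["delta"].clip(lower=0.0)
    df["decline"] = df["delta"].clip(upper=0.0)
    out = (
        df.groupby(["day_a", "day_b", "group"], as_index=False)
        .agg(growth_sum=("growth", "sum"), decline_sum=("decline", "sum"))
    )
    totals = (
        df.groupby(["day_a", "day_b"])
        .agg(
            total_growth=("growth", "sum"),
            total_decline=("decline", "sum"),
            total_change=("delta", "sum"),
        )
        .reset_index()
    )
    out = out.merge(totals, on=["day_a", "day_b"])
    with np.errstate(invalid="ignore", divide="ignore"):
        out["growth_share"] = np.where(
            out["total_growth"] > 0, out["growth_sum"] / out["total_growth"], np.nan
        )
        out["decline_share"] = np.where(
            out["total_decline"] < 0, out["decline_sum"] / out["total_decline"], np.nan
        )
    return out.drop(columns=["total_growth", "total_decline"])
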