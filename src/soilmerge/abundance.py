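"""Absolute abundances from relative abundances and total community sizes.

Amplicon sequencing yields compositional (relative) data only.  Scaling the
relative abundance r_i of taxon *i* in a sample by an independently measured
total community size N (cells g^-1 soil, from flow cytometry or CFU counts
of the same cell suspension) gives per-taxon absolute abundances
a_i = r_i * N, the quantity all demographic accounting here is based on.

DNA-based totals are converted to cell (genome-equivalent) counts through
an assumed mean genome weight per cell, which differs between community
origins (lake-derived communities carry smaller genomes on average than
soil-derived ones).
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .tables import relative_abundance

__all__ = [
    "DEFAULT_GENOME_MODEL",
    "absolute_abundance",
    "genome_equivalents",
    "transplant_summed_size",
    "infer_syncom_members",
    "SynComMembership",
]

#: Mean genome weight per cell in picograms, by community origin: lake-water
#: derived communities (LC) average smaller genomes than soil-derived ones
#: (SC).  Used to convert bulk DNA mass to genome equivalents.
DEFAULT_GENOME_MODEL: Mapping[str, float] = {"LC": 0.00292, "SC": 0.00511}

PG_PER_NG = 1000.0

_TOTAL_COLUMNS = {"fc": "fc_total", "cfu": "cfu_total"}


def _totals_for(rel: pd.DataFrame, sizes: pd.DataFrame, total: str) -> pd.Series:
    try:
        col = _TOTAL_COLUMNS[total]
    except KeyError:
        raise ValueError(f"total must be one of {sorted(_TOTAL_COLUMNS)}, got {total!r}")
    missing = rel.index.difference(sizes.index).tolist()
    if missing:
        raise ValueError(f"no community size record for sample(s): {missing[:5]}")
    totals = sizes.loc[rel.index, col]
    bad = totals.index[~(totals > 0)].tolist()
    if bad:
        raise ValueError(f"missing or non-positive {col} for sample(s): {bad[:5]}")
    return totals.astype(float)


def absolute_abundance(
    rel: pd.DataFrame, sizes: pd.DataFrame, total: str = "fc"
) -> pd.DataFrame:
    """Per-taxon absolute abundances a_i = r_i * N (cells g^-1).

    ``rel`` is a sample x taxon relative-abundance table; ``total`` selects
    which community-size estimate provides N ("fc" flow cytometry, the
    default because it is independent of culturing bias, or "cfu").  Each
    output row sums to that sample's N.
    """
    totals = _totals_for(rel, sizes, total)
    out = rel.mul(totals, axis=0)
    out.attrs["total_source"] = total
    return out


def genome_equivalents(
    dna_mass_ng: float | np.ndarray,
    community: str,
    genome_model: Mapping[str, float] = DEFAULT_GENOME_MODEL,
) -> float | np.ndarray:
    """Convert a DNA mass (ng) into genome-equivalent cell counts.

    cells = dna_mass [ng] * 1000 [pg/ng] / genome weight per cell [pg].
    """
    if community not in genome_model:
        raise KeyError(
            f"unknown community {community!r}; model covers {sorted(genome_model)}"
        )
    g_pg = genome_model[community]
    if g_pg <= 0:
        raise ValueError(f"genome weight for {community!r} must be positive")
    mass = np.asarray(dna_mass_ng, dtype=float)
    if (mass < 0).any():
        raise ValueError("DNA mass must be non-negative")
    cells = mass * PG_PER_NG / g_pg
    return float(cells) if np.isscalar(dna_mass_ng) else cells


def transplant_summed_size(
    counts: pd.DataFrame,
    sizes: pd.DataFrame,
    members: Iterable[str],
    total: str = "cfu",
) -> pd.Series:
    """Summed absolute abundance of the transplant members per sample.

    Sum over member ASVs of r_i * N; defaults to CFU totals (viable counts),
    the conventional scale for transplant-size tracking.  Samples where no
    member is detected give 0.
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("transplant member set is empty")
    unknown = [m for m in members if m not in counts.columns]
    if unknown:
        raise KeyError(f"member ASV(s) absent from count table: {unknown[:5]}")
    rel = relative_abundance(counts)
    totals = _totals_for(rel, sizes, total)
    out = rel[members].sum(axis=1) * totals
    out.name = "transplant_size"
    return out


class SynComMembership(NamedTuple):
    """Inferred transplant membership.

    ``members`` — ASVs detected in at least ``min_reps`` transplant-alone
    replicates; ``ambiguous`` — the subset of members also detected in a
    resident-alone condition (resident communities can carry the same ASVs
    as the transplant, so these cannot be attributed unambiguously).
    """

    members: frozenset[str]
    ambiguous: frozenset[str]


def infer_syncom_members(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    syncom_condition: str = "SynCom",
    resident_conditions: Iterable[str] | None = None,
    min_reps: int = 2,
) -> SynComMembership:
    """Derive the transplant ASV set from transplant-alone control samples.

    An ASV is a member if it has a nonzero count in at least ``min_reps``
    distinct replicates of the transplant-alone condition (any day).
    Members also detected in resident-alone conditions are flagged as
    ambiguous rather than silently assigned.
    """
    meta = metadata.loc[metadata.index.intersection(counts.index)]
    syn = meta[meta["condition"] == syncom_condition]
    if syn.empty:
        raise ValueError(f"no samples with condition {syncom_condition!r}")
    detected_reps = pd.DataFrame(
        {
            rep: (counts.loc[group.index] > 0).any(axis=0)
            for rep, group in syn.groupby("replicate")
        }
    )
    members = frozenset(detected_reps.index[detected_reps.sum(axis=1) >= min_reps])
    if resident_conditions is None:
        resident_conditions = [
            c
            for c in meta["condition"].unique()
            if c != syncom_condition and syncom_condition not in c.split("+")
        ]
    resident_samples = meta.index[meta["condition"].isin(list(resident_conditions))]
    if len(resident_samples):
        seen = counts.loc[resident_samples].sum(axis=0) > 0
        ambiguous = frozenset(m for m in members if seen.get(m, False))
    else:
        ambiguous = frozenset()
    return SynComMembership(members=members, ambiguous=ambiguous)
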