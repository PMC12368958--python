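"""Core data tables: read counts, taxonomy, sample metadata and community sizes.

All tabular data are plain :class:`pandas.DataFrame` objects with fixed
conventions rather than bespoke containers:

* **count table** — samples as rows (index named ``sample_id``), ASVs (or
  higher-rank taxa) as columns, non-negative integer read counts;
* **taxonomy map** — ASVs as rows (index ``asv_id``), columns ``genus`` and
  ``phylum``; missing classification is the explicit sentinel
  ``"unassigned"``, never NaN;
* **sample metadata** — samples as rows, columns ``condition`` (str),
  ``replicate`` (int) and ``day`` (number); (condition, replicate, day)
  uniquely identifies a sample;
* **community sizes** — samples as rows, columns ``fc_total`` (flow-cytometry
  cells g^-1), ``cfu_total`` (CFU g^-1, optional) and ``dna_conc``
  (ng DNA g^-1, optional); optional entries may be NaN but never negative.

On disk every table is a UTF-8, tab-separated file with the same
orientation; the first header cell names the index column.  The transposed
"#OTU ID" layout produced by BIOM TSV exports is detected and accepted by
:func:`read_count_table`.
"""

from __future__ import annotations

import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "UNASSIGNED",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_sizes",
    "write_sizes",
    "validate_count_table",
    "relative_abundance",
    "rarefy",
    "aggregate_to_rank",
    "shared_taxa_fraction",
]

#: Sentinel label for taxa without genus/phylum classification.
UNASSIGNED = "unassigned"

SAMPLE_INDEX = "sample_id"
ASV_INDEX = "asv_id"
METADATA_COLUMNS = ("condition", "replicate", "day")
SIZE_COLUMNS = ("fc_total", "cfu_total", "dna_conc")


# ---------------------------------------------------------------------------
# validation


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dupes[:5]}")


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate and return a canonical (int64) count table.

    Raises
    ------
    ValueError
        On duplicate sample/taxon ids, negative counts, or non-integer
        entries (the offending row and column are named).
    """
    _check_unique(counts.index, "sample")
    _check_unique(counts.columns, "taxon")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        # locate the first non-numeric cell for the error message
        coerced = counts.apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(coerced.isna().to_numpy() & counts.notna().to_numpy())
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-numeric count at sample {counts.index[r]!r}, "
                f"taxon {counts.columns[c]!r}"
            )
        values = coerced.to_numpy()
    if np.isnan(values.astype(float)).any():
        r, c = np.argwhere(np.isnan(values.astype(float)))[0]
        raise ValueError(
            f"missing count at sample {counts.index[r]!r}, taxon {counts.columns[c]!r}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at sample {counts.index[r]!r}, taxon {counts.columns[c]!r}"
        )
    if not np.issubdtype(values.dtype, np.integer):
        frac = np.mod(values.astype(float), 1.0)
        if (frac != 0).any():
            r, c = np.argwhere(frac != 0)[0]
            raise ValueError(
                f"non-integer count at sample {counts.index[r]!r}, "
                f"taxon {counts.columns[c]!r}"
            )
    out = counts.astype(np.int64)
    out.index = out.index.astype(str).rename(SAMPLE_INDEX)
    out.columns = out.columns.astype(str)
    return out


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, format: str = "auto") -> pd.DataFrame:
    """Read a sample x taxon count table from TSV.

    ``format`` may be ``"tsv"`` (canonical samples-as-rows layout),
    ``"biom-tsv"`` (BIOM TSV export: ``#OTU ID`` header, taxa as rows,
    samples as columns, optionally preceded by a ``# Constructed from biom
    file`` comment), or ``"auto"`` (detect from the header).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
        second = fh.readline()
    if format == "auto":
        if first.startswith("#OTU ID") or (
            first.startswith("#") and second.startswith("#OTU ID")
        ):
            format = "biom-tsv"
        else:
            format = "tsv"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "biom-tsv":
        skip = 1 if not first.startswith("#OTU ID") else 0
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip).T
    else:
        raise ValueError(f"unknown count-table format {format!r}")
    return validate_count_table(df)


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a count table in the canonical TSV layout (byte-stable)."""
    counts = validate_count_table(counts)
    counts.to_csv(Path(path), sep="\t", lineterminator="\n")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read an ASV -> (genus, phylum) map; empty fields become "unassigned"."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).rename(ASV_INDEX)
    for col in ("genus", "phylum"):
        if col not in df.columns:
            raise ValueError(f"taxonomy file {path} lacks a {col!r} column")
    df = df[["genus", "phylum"]].fillna(UNASSIGNED)
    df = df.replace("", UNASSIGNED)
    _check_unique(df.index, "ASV")
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    taxonomy.rename_axis(ASV_INDEX).to_csv(Path(path), sep="\t", lineterminator="\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (condition, replicate, day)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename(SAMPLE_INDEX)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} lacks columns {missing}")
    df = df[list(METADATA_COLUMNS)]
    df["condition"] = df["condition"].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    df["day"] = pd.to_numeric(df["day"])
    key = df[list(METADATA_COLUMNS)]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValueError(
            "metadata (condition, replicate, day) not unique: "
            f"{tuple(dup)} appears more than once"
        )
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.rename_axis(SAMPLE_INDEX).to_csv(Path(path), sep="\t", lineterminator="\n")


def read_sizes(path: str | Path) -> pd.DataFrame:
    """Read per-sample community sizes (fc_total, cfu_total, dna_conc)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).rename(SAMPLE_INDEX)
    if "fc_total" not in df.columns:
        raise ValueError(f"sizes file {path} lacks an 'fc_total' column")
    for col in SIZE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        if (df[col].dropna() < 0).any():
            raise ValueError(f"negative {col} in sizes file {path}")
    return df[list(SIZE_COLUMNS)]


def write_sizes(sizes: pd.DataFrame, path: str | Path) -> None:
    sizes.rename_axis(SAMPLE_INDEX).to_csv(Path(path), sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# table operations


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances (rows sum to 1).

    Raises
    ------
    ValueError
        If any sample row is all zeros (the sample is named).
    """
    totals = counts.sum(axis=1)
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"all-zero sample rows: {empty.index.tolist()[:5]}")
    return counts.div(totals, axis=0).astype(float)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # Per-sample stream keyed on (seed, crc32(sample_id)): the same sample is
    # subsampled identically whichever table subset it appears in.
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(str(sample_id).encode())])
    )


def rarefy(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each retained row is a multivariate hypergeometric draw of ``depth``
    reads from the observed reads.  Samples with fewer than ``depth`` total
    reads are dropped with a warning (subsampling cannot up-sample).
    Deterministic for a fixed ``seed``; the draw for a given sample does not
    depend on which other samples are present.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    counts = validate_count_table(counts)
    totals = counts.sum(axis=1)
    shallow = totals[totals < depth].index.tolist()
    if shallow:
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below rarefaction depth "
            f"{depth}: {shallow[:5]}",
            stacklevel=2,
        )
    kept = counts.loc[totals >= depth]
    rows = np.empty((len(kept), kept.shape[1]), dtype=np.int64)
    for i, (sid, row) in enumerate(kept.iterrows()):
        rng = _sample_rng(seed, sid)
        rows[i] = rng.multivariate_hypergeometric(
            row.to_numpy(), depth, method="marginals"
        )
    return pd.DataFrame(rows, index=kept.index, columns=kept.columns)


def aggregate_to_rank(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum ASV counts into genus or phylum columns.

    Unassigned taxa are pooled into an explicit ``"unassigned"`` column;
    per-sample totals are conserved exactly.
    """
    if rank not in ("genus", "phylum"):
        raise ValueError(f"rank must be 'genus' or 'phylum', got {rank!r}")
    missing = counts.columns.difference(taxonomy.index)
    if len(missing):
        raise KeyError(f"no taxonomy entry for ASV(s): {missing.tolist()[:5]}")
    labels = taxonomy.loc[counts.columns, rank].fillna(UNASSIGNED)
    grouped = counts.T.groupby(labels.to_numpy()).sum().T
    # preserve first-appearance column order
    order = list(dict.fromkeys(labels))
    return grouped[order]


def _observed_taxa(
    counts: pd.DataFrame, remove_singletons: bool
) -> set[str]:
    totals = counts.sum(axis=0)
    keep = totals > (1 if remove_singletons else 0)
    return set(totals.index[keep]) - {UNASSIGNED}


def shared_taxa_fraction(
    a: pd.DataFrame,
    b: pd.DataFrame,
    rank: str = "asv",
    taxonomy: pd.DataFrame | None = None,
    *,
    remove_singletons: bool = True,
    singletons_at: str = "rank",
) -> float:
    """Fraction of taxa in ``a`` that also occur in ``b``.

    Singletons (taxa with a total count of 1 within the table considered)
    and unassigned labels are removed before comparison; the denominator is
    the filtered taxon set of ``a`` (direction is explicit — swap the
    arguments for the other direction).

    For ``rank="genus"`` both tables are aggregated through ``taxonomy``
    first.  ``singletons_at`` selects whether singleton removal happens at
    the compared rank (``"rank"``, default) or at ASV level before
    aggregation (``"asv"``).
    """
    if rank not in ("asv", "genus"):
        raise ValueError(f"rank must be 'asv' or 'genus', got {rank!r}")
    if singletons_at not in ("rank", "asv"):
        raise ValueError(f"singletons_at must be 'rank' or 'asv', got {singletons_at!r}")
    if rank == "genus":
        if taxonomy is None:
            raise ValueError("taxonomy is required for rank='genus'")
        if remove_singletons and singletons_at == "asv":
            a = a.loc[:, a.sum(axis=0) != 1]
            b = b.loc[:, b.sum(axis=0) != 1]
            remove_at_rank = False
        else:
            remove_at_rank = remove_singletons
        a = aggregate_to_rank(a, taxonomy, "genus")
        b = aggregate_to_rank(b, taxonomy, "genus")
    else:
        remove_at_rank = remove_singletons
    set_a = _observed_taxa(a, remove_at_rank)
    set_b = _observed_taxa(b, remove_at_rank)
    if not set_a:
        raise ValueError("no taxa left in the reference table after filtering")
    return len(set_a & set_b) / len(set_a)


def sample_ids_for(
    metadata: pd.DataFrame,
    condition: str | None = None,
    replicate: int | None = None,
    day: float | None = None,
) -> list[str]:
    """Sample ids matching the given (condition, replicate, day) filters."""
    mask = pd.Series(True, index=metadata.index)
    if condition is not None:
        mask &= metadata["condition"] == condition
    if replicate is not None:
        mask &= metadata["replicate"] == replicate
    if day is not None:
        mask &= metadata["day"] == day
    return metadata.index[mask].tolist()
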