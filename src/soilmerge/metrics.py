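"""Supporting community metrics: Shannon diversity and Bray-Curtis distance."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

__all__ = ["shannon", "shannon_series", "bray_curtis", "bray_curtis_matrix"]


def _check_composition(r: np.ndarray, what: str) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError(f"{what} has negative entries")
    if not np.isclose(r.sum(), 1.0, atol=1e-9):
        raise ValueError(f"{what} does not sum to 1 (sum={r.sum()!r})")
    return r


def shannon(rel: pd.DataFrame | np.ndarray, sample: str | None = None, base: float | None = None) -> float:
    """Shannon index H = -sum(r_i * log r_i) of one sample's composition.

    Natural log by default (nats); pass ``base`` for another log base.
    """
    if isinstance(rel, pd.DataFrame):
        if sample is None:
            raise ValueError("sample id required when passing a table")
        r = rel.loc[sample].to_numpy()
    else:
        r = rel
    r = _check_composition(r, f"sample {sample!r}" if sample else "composition")
    r = r[r > 0]
    h = float(-np.sum(r * np.log(r)))
    if base is not None:
        h /= np.log(base)
    return h


def shannon_series(rel: pd.DataFrame, base: float | None = None) -> pd.Series:
    """Shannon index for every sample row of a relative-abundance table."""
    out = pd.Series(
        {sid: shannon(rel, sid, base=base) for sid in rel.index}, name="shannon"
    )
    out.index.name = rel.index.name
    return out


def bray_curtis(rel: pd.DataFrame, a: str, b: str) -> float:
    """Bray-Curtis dissimilarity BC = 1 - sum(min(r_a, r_b)) in [0, 1]."""
    ra = _check_composition(rel.loc[a].to_numpy(), f"sample {a!r}")
    rb = _check_composition(rel.loc[b].to_numpy(), f"sample {b!r}")
    return float(1.0 - np.minimum(ra, rb).sum())


def bray_curtis_matrix(rel: pd.DataFrame) -> pd.DataFrame:
    """Symmetric pairwise Bray-Curtis distance matrix over all samples."""
    vals = rel.to_numpy(dtype=float)
    sums = vals.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("empty sample row in relative-abundance table")
    n = len(rel)
    dm = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(vals[i], vals[i + 1 :]).sum(axis=1)
        dm[i, i + 1 :] = 1.0 - mins
    dm = dm + dm.T
    # guard against negative rounding noise
    dm = squareform(squareform(np.clip(dm, 0.0, 1.0), checks=False))
    return pd.DataFrame(dm, index=rel.index, columns=rel.index)
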