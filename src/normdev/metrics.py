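"""Individualized deviation metrics: outlier maps, counts, Hamming distances.

A region is an *outlier* for a participant when its deviation z-score
falls strictly below a negative threshold (default -1.96, the lower 2.5%
tail of the standard normal; documented alternate -1.282, the lower 10%).
Only the lower tail is flagged by default because the question is atrophy;
an opt-in two-tailed mode also flags z above ``|threshold|``.

The per-participant summary is the total outlier count (0..n_regions) and
the arithmetic mean of the regional z-scores.  Pattern dissimilarity
between two participants is the Hamming distance between their binary
outlier vectors; each participant's heterogeneity summary is the *median*
of their within-group pairwise distances (medians rather than means,
because the pairwise distributions are right-skewed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError

DEFAULT_THRESHOLD = -1.96
LIBERAL_THRESHOLD = -1.282


def binarize_outliers(
    z: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD, *, two_tailed: bool = False
) -> pd.DataFrame:
    """Binary outlier table: 1 where ``z < threshold`` (strict).

    ``threshold`` must be negative.  With ``two_tailed=True``, values
    above ``-threshold`` are flagged as well.
    """
    if not threshold < 0:
        raise ParameterError(f"outlier threshold must be negative, got {threshold}")
    vals = z.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError("z-score table contains non-finite values")
    o = vals < threshold
    if two_tailed:
        o |= vals > -threshold
    out = pd.DataFrame(o.astype(np.int8), index=z.index, columns=z.columns)
    out.attrs["threshold"] = threshold
    out.attrs["two_tailed"] = two_tailed
    return out


def summarize_participants(z: pd.DataFrame, o: pd.DataFrame) -> pd.DataFrame:
    """Per-participant total outlier count and mean regional z."""
    if z.shape != o.shape:
        raise DataError(f"z table shape {z.shape} != outlier table shape {o.shape}")
    return pd.DataFrame(
        {
            "total_outlier_count": o.to_numpy().sum(axis=1).astype(int),
            "mean_regional_z": z.to_numpy(dtype=float).mean(axis=1),
        },
        index=z.index,
    )


def regional_outlier_proportion(
    o: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region outlier proportion within each group.

    Returns ``(proportions, peaks)`` where ``proportions`` is regions x
    groups (values in [0, 1], region order preserved) and ``peaks`` lists,
    per group, the region with the highest outlier count and that count.
    """
    groups = pd.Series(np.asarray(groups), index=o.index)
    props = {}
    peaks = []
    for g, idx in groups.groupby(groups).groups.items():
        sub = o.loc[idx]
        p = sub.mean(axis=0)
        props[g] = p
        counts = sub.sum(axis=0)
        top = counts.idxmax()
        peaks.append({"group": g, "region": top, "n_outliers": int(counts[top]),
                      "proportion": float(p[top])})
    prop_df = pd.DataFrame(props, index=o.columns)
    prop_df.index.name = "region"
    return prop_df, pd.DataFrame(peaks).set_index("group")


@dataclass
class HammingResult:
    """Within-group pairwise Hamming distances and per-participant medians."""

    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, integer counts
    medians: pd.Series  # median of each participant's n-1 distances

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def pairwise_hamming(o: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distance matrix for binary rows of ``o``.

    Uses d(i, j) = k_i + k_j - 2 <o_i, o_j>, exact in integer arithmetic.
    """
    o = np.asarray(o, dtype=np.int64)
    k = o.sum(axis=1)
    g = o @ o.T
    return k[:, None] + k[None, :] - 2 * g


def hamming_matrix(o: pd.DataFrame, groups: pd.Series) -> dict[str, HammingResult]:
    """Within-group Hamming distance matrices plus per-participant medians.

    Every group must have at least two members (a singleton has no
    pairwise distances).
    """
    groups = pd.Series(np.asarray(groups), index=o.index)
    out: dict[str, HammingResult] = {}
    for g, idx in groups.groupby(groups).groups.items():
        sub = o.loc[idx]
        if len(sub) < 2:
            raise DataError(f"group {g!r} has fewer than 2 participants; "
                            "pairwise dissimilarity is undefined")
        mat = pairwise_hamming(sub.to_numpy())
        n = mat.shape[0]
        off = mat[~np.eye(n, dtype=bool)].reshape(n, n - 1)
        medians = pd.Series(np.median(off, axis=1), index=sub.index)
        out[str(g)] = HammingResult(ids=[str(i) for i in sub.index], matrix=mat, medians=medians)
    return out


def cross_group_hamming(o: pd.DataFrame, groups: pd.Series, a: str, b: str) -> np.ndarray:
    """Pairwise distances between members of group ``a`` (rows) and ``b``
    (columns).  Exposed for exploration; not part of the default report."""
    groups = pd.Series(np.asarray(groups), index=o.index)
    oa = o.loc[groups == a].to_numpy(np.int64)
    ob = o.loc[groups == b].to_numpy(np.int64)
    ka, kb = oa.sum(axis=1), ob.sum(axis=1)
    return ka[:, None] + kb[None, :] - 2 * (oa @ ob.T)
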