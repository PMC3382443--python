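"""Build unweighted graphs from expression matrices by correlation thresholding.

Vertices are probes; an edge weight is the Pearson correlation of two
probes' expression profiles across experimental conditions (or the
two-sided p-value of that correlation when the data contain missing
entries).  Thresholding at t keeps an edge when its correlation is at or
above t — or, for p-values, at or below t — giving the unweighted graph
the clique algorithms consume.

Correlations are computed over pairwise-complete conditions.  Probe pairs
with fewer than 3 complete observations or with zero variance have no
defined weight; they are omitted and recorded on the edge set.  Datasets
with fewer than 12 conditions produce unacceptably noisy correlations and
trigger a prominent warning (an error under ``strict=True``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import IO, Union

import numpy as np
import pandas as pd
from scipy import stats

from .graph import Graph, GraphError, label_sort_key

__all__ = [
    "ExpressionMatrix",
    "WeightedEdgeSet",
    "TransformError",
    "FewConditionsWarning",
    "log_transform",
    "correlate",
    "threshold_graph",
    "MIN_RECOMMENDED_CONDITIONS",
    "MIN_PAIR_SUPPORT",
]

MIN_RECOMMENDED_CONDITIONS = 12
MIN_PAIR_SUPPORT = 3


class TransformError(ValueError):
    """A value transform failed; the message names probe and condition."""


class FewConditionsWarning(UserWarning):
    """Fewer conditions than correlation thresholding can support reliably."""


class ExpressionMatrix:
    """Probes x conditions numeric table with explicit missing entries (NaN).

    Parameters
    ----------
    values
        DataFrame indexed by probe id with condition ids as columns.
    strict
        When True, fewer than 12 conditions is an error rather than a
        warning.
    """

    def __init__(self, values: pd.DataFrame, strict: bool = False):
        df = values.astype(float)
        if df.index.duplicated().any():
            raise GraphError("duplicate probe ids")
        if df.columns.duplicated().any():
            raise GraphError("duplicate condition ids")
        if df.shape[1] < 2:
            raise GraphError("an expression matrix needs at least 2 conditions")
        if df.shape[1] < MIN_RECOMMENDED_CONDITIONS:
            msg = (
                f"only {df.shape[1]} conditions; correlations thresholded on fewer "
                f"than {MIN_RECOMMENDED_CONDITIONS} conditions are unreliable"
            )
            if strict:
                raise GraphError(msg)
            warnings.warn(msg, FewConditionsWarning, stacklevel=2)
        self._df = df

    @classmethod
    def from_tsv(cls, source: Union[str, IO], strict: bool = False) -> "ExpressionMatrix":
        """Read a tab-separated matrix: first column probe id, header row of
        condition ids, empty cell or ``NA`` for missing."""
        df = pd.read_csv(source, sep="\t", index_col=0, na_values=["NA", ""])
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, strict=strict)

    @property
    def probe_ids(self) -> tuple:
        return tuple(self._df.index)

    @property
    def condition_ids(self) -> tuple:
        return tuple(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        return self._df

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self.probe_ids)} probes x {len(self.condition_ids)} conditions)"


@dataclass
class WeightedEdgeSet:
    """Probe-pair weights plus per-pair support and an omission log."""

    probes: tuple
    entries: dict[tuple, float]
    weight_kind: str  # "correlation" | "pvalue"
    pair_support: dict[tuple, int]
    omitted: list[tuple[tuple, str]] = field(default_factory=list)


def log_transform(X: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Replace every non-missing value by its logarithm (base 2 by default).

    Raises :class:`TransformError` naming the offending probe and
    condition if any non-missing value is not strictly positive.
    """
    df = X.values
    bad = (df <= 0).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise TransformError(
            f"non-positive value {df.iat[i, j]!r} at probe {df.index[i]!r}, "
            f"condition {df.columns[j]!r} cannot be log-transformed"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FewConditionsWarning)
        return ExpressionMatrix(np.log(df) / math.log(base))


def correlate(X: ExpressionMatrix, weight_kind: str = "correlation") -> WeightedEdgeSet:
    """Pearson weights for every probe pair over pairwise-complete conditions.

    ``weight_kind="pvalue"`` converts each correlation r with support s to
    the two-sided p-value of t = r * sqrt((s - 2) / (1 - r^2)) on s - 2
    degrees of freedom (p = 0 at |r| = 1).  Degenerate pairs (support < 3,
    zero variance) are omitted and logged, never errors.
    """
    if weight_kind not in ("correlation", "pvalue"):
        raise GraphError(f"unknown weight kind {weight_kind!r}")
    df = X.values.T  # conditions x probes
    corr = df.corr(method="pearson", min_periods=MIN_PAIR_SUPPORT)
    present = df.notna().to_numpy(dtype=np.int64)
    support_mat = present.T @ present

    probes = X.probe_ids
    pos = {p: i for i, p in enumerate(probes)}
    corr_arr = corr.reindex(index=list(probes), columns=list(probes)).to_numpy()
    entries: dict[tuple, float] = {}
    supports: dict[tuple, int] = {}
    omitted: list[tuple[tuple, str]] = []
    for a, b in itertools.combinations(sorted(probes, key=label_sort_key), 2):
        pair = (a, b)
        ia, ib = pos[a], pos[b]
        s = int(support_mat[ia, ib])
        r = corr_arr[ia, ib]
        if s < MIN_PAIR_SUPPORT:
            omitted.append((pair, f"support {s} < {MIN_PAIR_SUPPORT}"))
            continue
        if pd.isna(r):
            omitted.append((pair, "zero variance over complete conditions"))
            continue
        r = float(np.clip(r, -1.0, 1.0))
        supports[pair] = s
        if weight_kind == "correlation":
            entries[pair] = r
        else:
            if abs(r) >= 1.0:
                entries[pair] = 0.0
            else:
                t = abs(r) * math.sqrt((s - 2) / (1.0 - r * r))
                entries[pair] = float(2.0 * stats.t.sf(t, df=s - 2))
    return WeightedEdgeSet(tuple(probes), entries, weight_kind, supports, omitted)


def threshold_graph(
    W: WeightedEdgeSet,
    t: float,
    drop_isolated: bool = False,
    absolute: bool = False,
) -> Graph:
    """Unweighted graph of pairs at or above t (at or below for p-values).

    Both comparisons are inclusive.  ``absolute=True`` thresholds |r|
    instead of signed r (correlation kind only).  Probes without a
    surviving edge remain as isolated vertices unless ``drop_isolated``.
    """
    if W.weight_kind == "correlation":
        if not (-1.0 <= t <= 1.0):
            raise GraphError(f"correlation threshold {t} outside [-1, 1]")
        if absolute:
            keep = [p for p, w in W.entries.items() if abs(w) >= t]
        else:
            keep = [p for p, w in W.entries.items() if w >= t]
    elif W.weight_kind == "pvalue":
        if not (0.0 <= t <= 1.0):
            raise GraphError(f"p-value threshold {t} outside [0, 1]")
        keep = [p for p, w in W.entries.items() if w <= t]
    else:
        raise GraphError(f"unknown weight kind {W.weight_kind!r}")
    vertices = W.probes if not drop_isolated else ()
    return Graph(vertices, keep)
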