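"""Variance-preserving pairwise data extension.

From a sample xi_1..xi_n of a population with mean mu and variance sigma^2,
the pairwise construction

    eta_ij = mu + (xi_i + xi_j - 2*mu) / sqrt(2),    i < j,

yields n*(n-1)/2 new random variables, each with the same mean mu and
variance sigma^2; two eta sharing one source index correlate at 0.5, disjoint
pairs at 0, and eta_ij correlates with its own sources at 1/sqrt(2) (0 with
the others).  This lets a small feature table be extended into a training set
large enough for high-order polynomial regression while preserving the
first two moments and the class structure.

When the population mean is unknown (the applied case) the plug-in sample
mean is used; that perturbs the correlation structure at order 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import SchemaError, TooFewValuesError

__all__ = ["SampleColumn", "ExtendedColumn", "extend_column", "extend_table"]

_SQRT2 = np.sqrt(2.0)

#: feature-table columns extended per affect class (when present)
EXTENDABLE_COLUMNS = (
    "onset_time",
    "gain",
    "rise_time",
    "decay_time_constant",
    "valence",
    "arousal",
)

_RATING_COLUMNS = ("valence", "arousal")


@dataclass(frozen=True)
class SampleColumn:
    """A named sample xi_1..xi_n."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise SchemaError("sample must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(f"sample {self.label!r} contains non-finite values")


@dataclass(frozen=True)
class ExtendedColumn:
    """All n*(n-1)/2 pairwise extended values, lexicographic pair order."""

    values: np.ndarray
    pair_index: list[tuple[int, int]]
    label: str = ""


def pair_indices(n: int) -> list[tuple[int, int]]:
    """Unordered index pairs (i, j), i < j, in lexicographic order."""
    return list(combinations(range(n), 2))


def extend_column(sample, mu: float | None = None, label: str = "") -> ExtendedColumn:
    """Apply the pairwise extension to one sample column.

    Parameters
    ----------
    sample
        Array-like of n >= 2 finite values, or a :class:`SampleColumn`.
    mu
        Population mean to centre on.  ``None`` (default) uses the plug-in
        sample mean; pass the true mean when it is known (e.g. when checking
        the construction's moment/correlation claims by simulation).
    """
    if not isinstance(sample, SampleColumn):
        sample = SampleColumn(values=sample, label=label)
    x = sample.values
    n = len(x)
    if n < 2:
        raise TooFewValuesError(f"need at least 2 values to extend, got {n}")
    centre = float(np.mean(x)) if mu is None else float(mu)
    pairs = pair_indices(n)
    i_idx = np.fromiter((i for i, _ in pairs), dtype=int)
    j_idx = np.fromiter((j for _, j in pairs), dtype=int)
    eta = centre + (x[i_idx] + x[j_idx] - 2.0 * centre) / _SQRT2
    return ExtendedColumn(values=eta, pair_index=pairs, label=sample.label or label)


def extend_table(
    table: pd.DataFrame,
    group_column: str = "affect_class",
    columns: tuple[str, ...] | None = None,
    clip_ratings: bool = True,
) -> pd.DataFrame:
    """Extend every feature column of a table within each affect class.

    The same pair index (i, j) is used across all columns of a class, so each
    simulated row is an internally consistent pseudo-stimulus; this preserves
    the joint (gain, decay-constant, rating) pattern of the class.  Each
    class contributes n*(n-1)/2 rows for its n source rows.

    Rating columns are clipped back into [1, 9] (the extension can overshoot
    the scale ends slightly); set ``clip_ratings=False`` to keep raw values.

    Returns a table with the source schema plus a ``source_pair`` provenance
    column; ``provenance`` is set to ``"simulated"``.
    """
    if group_column not in table.columns:
        raise SchemaError(f"missing group column {group_column!r}")
    if columns is None:
        columns = tuple(c for c in EXTENDABLE_COLUMNS if c in table.columns)
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns to extend: {missing}")

    out_frames = []
    for cls, grp in table.groupby(group_column, sort=False):
        if len(grp) < 2:
            raise TooFewValuesError(
                f"class {cls!r} has {len(grp)} row(s); need at least 2"
            )
        pairs = pair_indices(len(grp))
        ids = grp["stimulus_id"].astype(str).to_numpy() if "stimulus_id" in grp \
            else np.array([str(k) for k in range(len(grp))])
        rows = pd.DataFrame(index=range(len(pairs)))
        rows[group_column] = cls
        if "stimulus_id" in table.columns:
            rows["stimulus_id"] = [f"{cls}:{ids[i]}+{ids[j]}" for i, j in pairs]
        for col in columns:
            ext = extend_column(grp[col].to_numpy(dtype=float), label=col)
            vals = ext.values
            if clip_ratings and col in _RATING_COLUMNS:
                vals = np.clip(vals, 1.0, 9.0)
            rows[col] = vals
        rows["provenance"] = "simulated"
        rows["source_pair"] = [f"{ids[i]},{ids[j]}" for i, j in pairs]
        out_frames.append(rows)

    out = pd.concat(out_frames, ignore_index=True)
    # keep source column order where possible, extras at the end
    ordered = [c for c in table.columns if c in out.columns]
    ordered += [c for c in out.columns if c not in ordered]
    return out[ordered]
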