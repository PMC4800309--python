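"""CSV / trace / model file I/O with schema validation.

Feature tables are CSV with the columns

    stimulus_id, affect_class, onset_time, gain, rise_time,
    decay_time_constant, valence, arousal[, provenance, ...]

in seconds / microsiemens / 1-9 rating units; unknown extra columns are
preserved on round trips.  Raw traces are two-column delimited text
(time_s, conductance_uS) with an optional header.  Polynomial models use the
text serialization from :mod:`affectscr.hmpr`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError
from .hmpr import PolynomialModel, load_model
from .scr import SCTrace

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_feature_table",
    "read_feature_table",
    "write_feature_table",
    "read_trace",
    "write_trace",
    "load_published_model",
]

REQUIRED_COLUMNS = (
    "stimulus_id", "affect_class", "onset_time", "gain", "rise_time",
    "decay_time_constant", "valence", "arousal",
)

_POSITIVE_COLUMNS = ("gain", "rise_time", "decay_time_constant")
_NONNEG_COLUMNS = ("onset_time",)
_RATING_COLUMNS = ("valence", "arousal")


def validate_feature_table(table: pd.DataFrame,
                           required=REQUIRED_COLUMNS) -> None:
    """Raise on schema or invariant violations, listing every failure."""
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns: {missing}")
    failures: list[str] = []
    for col in _RATING_COLUMNS:
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals < 1) | (vals > 9) | vals.isna()]
        failures += [f"{col}[row {i}]={table.at[i, col]!r} outside [1, 9]"
                     for i in bad]
    for col, floor_open in [(c, True) for c in _POSITIVE_COLUMNS] + \
                           [(c, False) for c in _NONNEG_COLUMNS]:
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals <= 0 if floor_open else vals < 0) | vals.isna()]
        failures += [f"{col}[row {i}]={table.at[i, col]!r} must be "
                     f"{'> 0' if floor_open else '>= 0'}" for i in bad]
    if "stimulus_id" in table.columns:
        prov = table["provenance"] if "provenance" in table.columns \
            else pd.Series("experimental", index=table.index)
        dup = table[["stimulus_id"]].assign(_p=prov).duplicated()
        failures += [f"duplicate stimulus_id {table.at[i, 'stimulus_id']!r} "
                     f"within provenance" for i in table.index[dup]]
    if failures:
        raise ValidationError("feature table invalid: " + "; ".join(failures))


def read_feature_table(path, validate: bool = True) -> pd.DataFrame:
    """Read a feature-table CSV; a missing provenance column defaults to
    ``experimental``."""
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # surface parse problems as package errors
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if "provenance" not in table.columns:
        table["provenance"] = "experimental"
    if validate:
        validate_feature_table(table)
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write at full precision (floats as repr: lossless round trip)."""
    table.to_csv(path, index=False)


def read_trace(path, sampling_rate: float | None = None) -> SCTrace:
    """Read a two-column (time_s, conductance_uS) text trace.

    The delimiter (comma or whitespace) and an optional single header line
    are auto-detected.  ``sampling_rate`` overrides the rate inferred from
    the time column.
    """
    text = Path(path).read_text().strip().splitlines()
    rows = []
    for ln, line in enumerate(text):
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise SchemaError(f"{path}: line {ln + 1} has fewer than 2 columns")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if ln == 0:
                continue  # header
            raise SchemaError(f"{path}: line {ln + 1} is not numeric") from None
    if not rows:
        raise SchemaError(f"{path}: no data rows")
    arr = np.asarray(rows)
    times, values = arr[:, 0], arr[:, 1]
    if sampling_rate is None:
        if len(times) < 2:
            raise SchemaError("cannot infer sampling rate from one sample")
        sampling_rate = 1.0 / float(np.mean(np.diff(times)))
    return SCTrace(times=times, values=values, sampling_rate=float(sampling_rate))


def write_trace(trace: SCTrace, path, header: bool = True) -> None:
    lines = ["time_s,conductance_uS"] if header else []
    lines += [f"{float(t)!r},{float(v)!r}"
              for t, v in zip(trace.times, trace.values)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_published_model(path, target_label: str | None = None) -> PolynomialModel:
    """Load a serialized affective polynomial model (e.g. published
    coefficients over gain and decay time constant) with validation.

    Duplicate exponent tuples or degrees above the declared order raise a
    validation error inside the model constructor; a ``target_label``
    mismatch raises here.
    """
    model = load_model(path)
    if target_label is not None and model.target_label \
            and model.target_label != target_label:
        raise ValidationError(
            f"model targets {model.target_label!r}, expected {target_label!r}"
        )
    return model
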