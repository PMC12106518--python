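"""Curve containers and plain-text I/O.

A CurveTable holds one loading curve: (strain, stress) for tensile tests
(MPa) or (curvature, moment) for bending (1/mm, N mm), plus specimen
metadata (id, test type, age, sex, ...). On disk a curve is a two-column
CSV with the exact header ``strain,stress`` or ``curvature,moment``; the
metadata travels in a sidecar JSON file ``<name>.meta.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

_HEADERS = {"tension": ("strain", "stress"), "bending": ("curvature", "moment")}


@dataclass
class CurveTable:
    """Ordered samples of one loading curve with specimen metadata."""

    abscissa: np.ndarray
    ordinate: np.ndarray
    kind: str = "tension"  # 'tension' or 'bending'
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        if self.kind not in _HEADERS:
            raise ValidationError(f"curve kind must be one of {sorted(_HEADERS)}, got {self.kind!r}")
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.ordinate.shape:
            raise ValidationError("abscissa and ordinate must be 1-d arrays of equal length")
        if len(self.abscissa) == 0:
            raise ValidationError("curve must contain at least one sample")
        if self.abscissa[0] != 0.0 or self.ordinate[0] != 0.0:
            raise ValidationError("curve must start at the origin (0, 0)")
        if len(self.abscissa) > 1 and not np.all(np.diff(self.abscissa) > 0.0):
            raise ValidationError("curve abscissa must be strictly increasing")

    def __len__(self) -> int:
        return len(self.abscissa)

    @property
    def columns(self) -> tuple[str, str]:
        return _HEADERS[self.kind]

    def to_frame(self) -> pd.DataFrame:
        x, y = self.columns
        return pd.DataFrame({x: self.abscissa, y: self.ordinate})


def write_curve(curve: CurveTable, path) -> None:
    """Write the curve CSV and its metadata sidecar JSON."""
    path = Path(path)
    curve.to_frame().to_csv(path, index=False, float_format="%.12g")
    meta = dict(curve.metadata)
    meta["kind"] = curve.kind
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def _reject_bad_rows(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = np.where(coerced.isna())[0]
            if len(bad):
                line = int(bad[0]) + 2  # header is line 1
                val = df[col].iloc[bad[0]]
                hint = ""
                if isinstance(val, str) and "," in val:
                    hint = " (decimal commas are not accepted; use '.' as decimal separator)"
                raise ValidationError(
                    f"{path}: non-numeric value {val!r} in column {col!r} at line {line}{hint}"
                )
            df[col] = coerced
        nan_rows = np.where(df[col].isna())[0]
        if len(nan_rows):
            raise ValidationError(
                f"{path}: missing value in column {col!r} at line {int(nan_rows[0]) + 2}"
            )


def read_curve(path) -> CurveTable:
    """Read a curve CSV (+ sidecar metadata if present) with validation."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"curve file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"could not parse {path} as CSV: {exc}") from exc
    cols = tuple(df.columns)
    kind = next((k for k, hdr in _HEADERS.items() if cols == hdr), None)
    if kind is None:
        raise ValidationError(
            f"{path}: expected header 'strain,stress' or 'curvature,moment', got {list(cols)}"
        )
    _reject_bad_rows(df, cols, path)

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    metadata: dict = {}
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
        metadata.pop("kind", None)
    try:
        return CurveTable(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), kind, metadata)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot
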