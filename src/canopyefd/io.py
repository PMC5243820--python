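"""CSV/PNG serialization of contours, descriptor tables, and masks.

All tables are written with ``%.17g`` floats so a write/read round trip is
lossless at float64 precision.  Schemas are validated on read, with errors
naming the missing/extra columns.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from canopyefd.efd import EFDSet, StandardizedEFD

__all__ = [
    "SchemaError",
    "write_mask",
    "read_mask",
    "write_contour",
    "read_contour",
    "efd_table",
    "efd_from_table",
    "standardized_table",
    "standardized_from_table",
    "write_table",
    "read_table",
    "validate_columns",
    "efd_record_bytes",
]

FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A table does not match its expected column schema."""


def validate_columns(df: pd.DataFrame, expected: list[str], allow_extra: bool = False) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or (extra and not allow_extra):
        raise SchemaError(f"schema mismatch: missing={missing}, extra={extra}")


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool).astype(np.uint8) * 255))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_contour(path, contour: np.ndarray) -> None:
    contour = np.asarray(contour, dtype=float)
    pd.DataFrame({
        "point_index": np.arange(len(contour)),
        "x": contour[:, 0],
        "y": contour[:, 1],
    }).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_contour(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    validate_columns(df, ["point_index", "x", "y"])
    df = df.sort_values("point_index")
    return df[["x", "y"]].to_numpy(dtype=float)


def _coeff_columns(n_harmonics: int) -> list[str]:
    cols = []
    for n in range(1, n_harmonics + 1):
        cols += [f"a_{n}", f"b_{n}", f"c_{n}", f"d_{n}"]
    return cols


def efd_table(ids, efds) -> pd.DataFrame:
    """One row per canopy: id, A0, C0, T, a_1..d_N."""
    efds = list(efds)
    n_set = {e.n_harmonics for e in efds}
    if len(n_set) != 1:
        raise SchemaError("EFD records have differing harmonic counts")
    n = n_set.pop()
    data = {
        "id": list(ids),
        "A0": [e.A0 for e in efds],
        "C0": [e.C0 for e in efds],
        "T": [e.T for e in efds],
    }
    coeffs = np.stack([e.coeffs.ravel() for e in efds])
    for j, col in enumerate(_coeff_columns(n)):
        data[col] = coeffs[:, j]
    return pd.DataFrame(data)


def efd_from_table(df: pd.DataFrame) -> tuple[list, list[EFDSet]]:
    """Inverse of :func:`efd_table`."""
    coeff_cols = [c for c in df.columns if c[:2] in {"a_", "b_", "c_", "d_"}]
    n = len(coeff_cols) // 4
    validate_columns(df, ["id", "A0", "C0", "T"] + _coeff_columns(n))
    efds = []
    for _, row in df.iterrows():
        coeffs = row[_coeff_columns(n)].to_numpy(dtype=float).reshape(n, 4)
        efds.append(EFDSet(A0=float(row["A0"]), C0=float(row["C0"]), coeffs=coeffs,
                           T=float(row["T"])))
    return df["id"].tolist(), efds


def standardized_table(ids, records) -> pd.DataFrame:
    """Standardized layout: id, L, psi, theta, A0, C0, xm, ym, a_1..d_N."""
    records = list(records)
    n_set = {r.n_harmonics for r in records}
    if len(n_set) != 1:
        raise SchemaError("standardized records have differing harmonic counts")
    n = n_set.pop()
    data = {
        "id": list(ids),
        "L": [r.L for r in records],
        "psi": [r.psi for r in records],
        "theta": [r.theta for r in records],
        "A0": [r.A0 for r in records],
        "C0": [r.C0 for r in records],
        "xm": [r.xm for r in records],
        "ym": [r.ym for r in records],
    }
    coeffs = np.stack([r.coeffs.ravel() for r in records])
    for j, col in enumerate(_coeff_columns(n)):
        data[col] = coeffs[:, j]
    return pd.DataFrame(data)


def standardized_from_table(df: pd.DataFrame) -> tuple[list, list[StandardizedEFD]]:
    coeff_cols = [c for c in df.columns if c[:2] in {"a_", "b_", "c_", "d_"}]
    n = len(coeff_cols) // 4
    validate_columns(df, ["id", "L", "psi", "theta", "A0", "C0", "xm", "ym"] + _coeff_columns(n))
    records = []
    for _, row in df.iterrows():
        coeffs = row[_coeff_columns(n)].to_numpy(dtype=float).reshape(n, 4)
        records.append(StandardizedEFD(
            coeffs=coeffs, L=float(row.L), psi=float(row.psi), theta=float(row.theta),
            A0=float(row.A0), C0=float(row.C0), xm=float(row.xm), ym=float(row.ym),
        ))
    return df["id"].tolist(), records


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_table(path, expected: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if expected is not None:
        validate_columns(df, expected, allow_extra=True)
    return df


def efd_record_bytes(efd: EFDSet, dtype=np.float32) -> bytes:
    """Compact binary serialization of one descriptor record.

    Packs (A0, C0, T, a_1..d_N) as a flat array; used to audit the storage
    footprint of the descriptor representation against the source image.
    """
    flat = np.concatenate([[efd.A0, efd.C0, efd.T], efd.coeffs.ravel()]).astype(dtype)
    buf = _io.BytesIO()
    np.save(buf, flat)
    return buf.getvalue()
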