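"""Reading and writing cytometry matrices and label files.

Supports CSV (cells as rows, header row of marker names) and list-mode
FCS 3.0/3.1 files.  The FCS support is a deliberately minimal, standard-
conforming reader/writer for the common case: HEADER with ASCII segment
offsets, a delimited TEXT segment, and a single list-mode DATA segment of
float (``$DATATYPE F``/``D``) or unsigned integer (``$DATATYPE I``) events
in little- or big-endian byte order.  Analysis segments, multi-data-set
files and delimiter escaping inside keyword values are not supported.

Also provides the standard cytometry preprocessing transform
``asinh(x / cofactor)`` with the conventional cofactor of 5.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._grid import ExpressionMatrix

__all__ = [
    "read_matrix",
    "read_csv_matrix",
    "read_fcs",
    "write_fcs",
    "arcsinh_transform",
    "write_labels",
    "read_labels",
]


def arcsinh_transform(matrix, cofactor: float = 5.0):
    """Elementwise ``asinh(x / cofactor)``.

    The inverse hyperbolic sine compresses high intensities
    logarithmically while staying approximately linear near zero, which is
    the standard variance-stabilising preprocessing for flow and mass
    cytometry; the conventional cofactor is 5.

    Accepts an :class:`ExpressionMatrix` (returns a new one) or a plain
    array.
    """
    if not cofactor > 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(
            values=np.arcsinh(matrix.values / cofactor),
            marker_names=matrix.marker_names,
        )
    return np.arcsinh(np.asarray(matrix, dtype=np.float64) / cofactor)


def _select_columns(frame: pd.DataFrame, columns) -> pd.DataFrame:
    if columns is None:
        return frame
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise KeyError(
            f"column(s) {missing} not found; available: {list(frame.columns)}"
        )
    return frame[list(columns)]


def read_csv_matrix(path, columns=None) -> ExpressionMatrix:
    """Read a CSV expression matrix (header row of marker names required)."""
    frame = pd.read_csv(path)
    frame = _select_columns(frame, columns)
    return ExpressionMatrix(
        values=frame.to_numpy(dtype=np.float64),
        marker_names=tuple(str(c) for c in frame.columns),
    )


def read_matrix(path, format: str | None = None, columns=None) -> ExpressionMatrix:
    """Read an expression matrix from CSV or FCS.

    Parameters
    ----------
    path
        Input file.
    format
        ``"csv"`` or ``"fcs"``; inferred from the file suffix when None.
    columns
        Optional marker names to select, in the requested order; an
        unknown name raises ``KeyError`` naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such input file: {path}")
    if format is None:
        format = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if format == "csv":
        return read_csv_matrix(path, columns)
    if format == "fcs":
        return read_fcs(path, columns)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'fcs'")


# ---------------------------------------------------------------------------
# Minimal FCS 3.0/3.1 support

_HEADER_LEN = 58  # version (6) + 4 spaces + six 8-char ASCII offsets


def _parse_text_segment(raw: bytes) -> dict:
    delim = raw[:1]
    if not delim:
        raise ValueError("empty FCS TEXT segment")
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2:
        raise ValueError("malformed FCS TEXT segment: odd number of tokens")
    return {
        parts[i].decode("ascii", "replace").strip().upper(): parts[i + 1]
        .decode("ascii", "replace")
        .strip()
        for i in range(0, len(parts), 2)
    }


def read_fcs(path, columns=None) -> ExpressionMatrix:
    """Read a list-mode FCS 3.0/3.1 file into an expression matrix."""
    data = Path(path).read_bytes()
    if len(data) < _HEADER_LEN or not data[:3] == b"FCS":
        raise ValueError(f"{path}: not an FCS file")
    version = data[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo, hi):
        field = data[lo:hi].decode("ascii", "replace").strip()
        return int(field) if field else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    kw = _parse_text_segment(data[text_start : text_end + 1])

    if kw.get("$MODE", "L") != "L":
        raise ValueError(f"{path}: only list-mode ($MODE L) FCS is supported")
    if data_start == 0:
        data_start = int(kw["$BEGINDATA"])
        data_end = int(kw["$ENDDATA"])
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    if byteord == "1,2,3,4":
        order = "<"
    elif byteord == "4,3,2,1":
        order = ">"
    else:
        raise ValueError(f"{path}: unsupported $BYTEORD {byteord!r}")
    datatype = kw.get("$DATATYPE", "F")
    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        bits = {int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise ValueError(
                f"{path}: integer data requires uniform $PnB of 16 or 32"
            )
        width = int(kw["$P1B"]) // 8
        dtype = np.dtype(f"{order}u{width}")
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r}")

    raw = data[data_start : data_end + 1]
    expected = n_tot * n_par * dtype.itemsize
    if len(raw) < expected:
        raise ValueError(
            f"{path}: DATA segment holds {len(raw)} bytes, "
            f"expected {expected} for {n_tot} events x {n_par} parameters"
        )
    values = (
        np.frombuffer(raw[:expected], dtype=dtype)
        .reshape(n_tot, n_par)
        .astype(np.float64)
    )
    names = tuple(kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1))
    frame = pd.DataFrame(values, columns=names)
    frame = _select_columns(frame, columns)
    return ExpressionMatrix(
        values=frame.to_numpy(dtype=np.float64),
        marker_names=tuple(frame.columns),
    )


def write_fcs(path, matrix, marker_names=None) -> None:
    """Write an FCS 3.0 file with a single float32 list-mode data segment."""
    if isinstance(matrix, ExpressionMatrix):
        values, names = matrix.values, matrix.marker_names
    else:
        values = np.asarray(matrix, dtype=np.float64)
        names = tuple(marker_names or (f"P{i+1}" for i in range(values.shape[1])))
    n_tot, n_par = values.shape
    for name in names:
        if "/" in name:
            raise ValueError(f"marker name {name!r} contains the TEXT delimiter '/'")

    payload = values.astype("<f4").tobytes()
    kw = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(names, start=1):
        rng = values[:, i - 1].max() if n_tot else 0.0
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = str(int(np.ceil(abs(rng))) + 1)

    # fixed-width data offsets keep the TEXT length independent of their value
    kw["$BEGINDATA"] = "0" * 10
    kw["$ENDDATA"] = "0" * 10
    delim = "/"

    def _render(d):
        return (delim + delim.join(f"{k}{delim}{v}" for k, v in d.items()) + delim).encode("ascii")

    text = _render(kw)
    text_start = _HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1
    kw["$BEGINDATA"] = f"{data_start:010d}"
    kw["$ENDDATA"] = f"{data_end:010d}"
    text = _render(kw)

    header = (
        f"{'FCS3.0':<10}"
        f"{text_start:>8}{text_end:>8}"
        f"{data_start if data_start <= 99_999_999 else 0:>8}"
        f"{data_end if data_end <= 99_999_999 else 0:>8}"
        f"{0:>8}{0:>8}"
    ).encode("ascii")
    assert len(header) == _HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


# ---------------------------------------------------------------------------
# Label files


def write_labels(labels, path) -> None:
    """Write per-cell cluster labels as CSV: ``cell_index,label``.

    ``labels`` may be a :class:`~flowgrid.cluster.ClusterLabels` or any
    integer vector; outliers carry the label -1.
    """
    vec = getattr(labels, "cell_label", labels)
    vec = np.asarray(vec, dtype=np.int64)
    frame = pd.DataFrame({"cell_index": np.arange(vec.shape[0]), "label": vec})
    frame.to_csv(path, index=False)


def read_labels(path, column: str | None = None) -> np.ndarray:
    """Read an integer label vector.

    Accepts either a headerless file with one integer per line, or a CSV
    with a header, in which case ``column`` selects the label column
    (default: ``"label"`` if present, else the last column).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    token = first.split(",")[0]
    try:
        int(token)
        headerless = True
    except ValueError:
        headerless = False
    if headerless:
        return pd.read_csv(path, header=None).iloc[:, 0].to_numpy(np.int64)
    frame = pd.read_csv(path)
    if column is None:
        column = "label" if "label" in frame.columns else frame.columns[-1]
    if column not in frame.columns:
        raise KeyError(
            f"column {column!r} not found; available: {list(frame.columns)}"
        )
    return frame[column].to_numpy(np.int64)
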