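"""Readers and writers for the standard formats the pipeline touches.

Streamline bundles travel as TCK files, scalar microstructure maps (e.g. FA)
as NIfTI-1 volumes, and behavioral/QC tables as tab-separated text.  All
geometry is expressed in RAS world coordinates in millimeters; voxel indices
are 0-based and interpolation happens in continuous voxel space after
applying the inverse affine.

The heavy lifting for the binary formats is delegated to :mod:`nibabel`;
this module adds the validation and error reporting the pipeline relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

__all__ = [
    "Bundle",
    "ScalarVolume",
    "FormatError",
    "TableSchemaError",
    "read_streamlines",
    "write_streamlines",
    "read_scalar_volume",
    "write_scalar_volume",
    "sample_trilinear",
    "read_draw_trials",
    "write_draw_trials",
    "read_recognition_trials",
    "write_recognition_trials",
    "read_qc_table",
    "write_qc_table",
    "write_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1"


class FormatError(ValueError):
    """A streamline or volume file violates its format contract."""


class TableSchemaError(ValueError):
    """A delimited-text table is missing columns or has unparseable cells."""


def validate_streamline(points: np.ndarray) -> np.ndarray:
    """Check a single streamline: >= 2 finite 3-D points, nonzero segments."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise FormatError(f"streamline must be an (n>=2, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise FormatError("streamline contains non-finite coordinates")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise FormatError("streamline has consecutive duplicate points (zero-length segment)")
    return pts


@dataclass
class Bundle:
    """A named, hemisphere-tagged set of streamlines for one tract of one participant."""

    tract_name: str
    hemisphere: str
    participant_id: str
    streamlines: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right", ""):
            raise ValueError(f"hemisphere must be left/right/'', got {self.hemisphere!r}")
        self.streamlines = [validate_streamline(s) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths_mm(self) -> np.ndarray:
        """Chord length (sum of segment lengths) of each streamline."""
        return np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines]
        )


@dataclass
class ScalarVolume:
    """A 3-D scalar grid (e.g. FA) with a voxel-index -> mm affine."""

    values: np.ndarray
    affine: np.ndarray
    background: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise FormatError(f"scalar volume must be 3-D, got {self.values.ndim}-D")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("scalar volume contains non-finite values")


# ---------------------------------------------------------------------------
# TCK streamlines


def read_streamlines(
    path: str | Path,
    tract_name: str = "",
    hemisphere: str = "",
    participant_id: str = "",
) -> Bundle:
    """Read a TCK file into a :class:`Bundle` (coordinates in RAS mm)."""
    path = Path(path)
    try:
        tractogram_file = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises HeaderError/DataError subclasses
        raise FormatError(f"{path}: cannot parse TCK file: {exc}") from exc
    if not isinstance(tractogram_file, nib.streamlines.TckFile):
        raise FormatError(f"{path}: not a TCK streamline file")
    header = tractogram_file.header
    offset = int(header.get("_offset_data", 0))
    streamlines = [np.asarray(s, dtype=float) for s in tractogram_file.streamlines]
    n_points_seen = 0
    for i, s in enumerate(streamlines):
        if not np.all(np.isfinite(s)):
            bad = n_points_seen + int(np.argmax(~np.isfinite(s).all(axis=1)))
            raise FormatError(
                f"{path}: non-finite coordinate inside streamline {i} "
                f"(near byte offset {offset + 12 * (bad + i)})"
            )
        try:
            validate_streamline(s)
        except FormatError as exc:
            raise FormatError(f"{path}: streamline {i}: {exc}") from exc
        n_points_seen += len(s)
    return Bundle(
        tract_name=tract_name,
        hemisphere=hemisphere,
        participant_id=participant_id,
        streamlines=streamlines,
    )


def write_streamlines(bundle: Bundle, path: str | Path) -> None:
    """Write a bundle as a TCK file (Float32LE payload, count header set)."""
    for i, s in enumerate(bundle.streamlines):
        if len(s) == 0:
            raise ValueError(f"streamline {i} has an empty point list")
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in bundle.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(tractogram, str(path))


# ---------------------------------------------------------------------------
# NIfTI scalar volumes


def read_scalar_volume(path: str | Path, background: float = 0.0) -> ScalarVolume:
    """Read a 3-D NIfTI-1 scalar image."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: cannot read NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if np.iscomplexobj(data):
        raise FormatError(f"{path}: complex-valued images are unsupported")
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D scalar image, got {data.ndim}-D")
    return ScalarVolume(values=data.astype(float), affine=np.asarray(img.affine), background=background)


def write_scalar_volume(volume: ScalarVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.values, volume.affine), str(path))


def sample_trilinear(
    volume: ScalarVolume, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinearly sample a volume at world-space (mm) points.

    Returns ``(values, out_of_bounds)``.  Points outside the voxel grid
    (continuous voxel coordinate outside ``[0, dim-1]`` on any axis) get the
    volume's declared background value and are flagged; they never raise.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 3:
        raise ValueError(f"points must be (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite sample point")
    inv = np.linalg.inv(volume.affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    dims = np.array(volume.values.shape)
    oob = np.any((vox < 0) | (vox > dims - 1), axis=1)
    values = map_coordinates(volume.values, vox.T, order=1, mode="nearest")
    values = np.where(oob, volume.background, values)
    if single:
        return values[0], oob[0]
    return values, oob


# ---------------------------------------------------------------------------
# Behavioral / QC tables (tab-separated text with documented headers)

DRAW_COLUMNS = {
    "participant_id": str,
    "symbol_id": int,
    "repetition": int,
    "chronological_index": int,
    "draw_duration": float,
}
RECOGNITION_COLUMNS = {
    "participant_id": str,
    "symbol_id": int,
    "is_target": bool,
    "responded": bool,
    "correct": bool,
    "rt": float,
}
QC_COLUMNS = {
    "participant_id": str,
    "snr": float,
    "fd": float,
    "artifact_flag": bool,
}

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False, "": None}


def _parse_table(path: str | Path, schema: dict[str, type]) -> pd.DataFrame:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing required column(s) {missing}")
    out = {}
    for col, typ in schema.items():
        series = raw[col]
        if typ is str:
            out[col] = series.astype(str)
            continue
        if typ is bool:
            vals = []
            for i, cell in enumerate(series):
                key = cell.strip().lower()
                if key not in _BOOL_MAP:
                    raise TableSchemaError(
                        f"{path}: row {i + 1}: cannot parse {col}={cell!r} as boolean"
                    )
                vals.append(_BOOL_MAP[key])
            out[col] = pd.array(vals, dtype="boolean")
            continue
        converted = pd.to_numeric(series.replace("", np.nan), errors="coerce")
        bad = converted.isna() & (series.str.strip() != "")
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise TableSchemaError(
                f"{path}: row {row + 1}: cannot parse {col}={series.iloc[row]!r}"
            )
        out[col] = converted.astype(float) if typ is float else converted.astype("Int64")
    return pd.DataFrame(out)


def read_draw_trials(path: str | Path) -> pd.DataFrame:
    """Read drawing-training trials; one row per trial, order preserved."""
    df = _parse_table(path, DRAW_COLUMNS)
    df["symbol_id"] = df["symbol_id"].astype(int)
    df["repetition"] = df["repetition"].astype(int)
    df["chronological_index"] = df["chronological_index"].astype(int)
    return df


def read_recognition_trials(path: str | Path) -> pd.DataFrame:
    """Read 2-AFC recognition trials.

    ``correct`` and ``rt`` are defined only for responded trials (empty cells
    otherwise, surfacing as missing values).
    """
    df = _parse_table(path, RECOGNITION_COLUMNS)
    df["symbol_id"] = df["symbol_id"].astype(int)
    responded = df["responded"].fillna(False).astype(bool)
    df["responded"] = responded
    defined = df["correct"].notna().to_numpy()
    if np.any(defined != responded.to_numpy()):
        raise TableSchemaError(f"{path}: 'correct' must be defined iff 'responded'")
    return df


def read_qc_table(path: str | Path) -> pd.DataFrame:
    df = _parse_table(path, QC_COLUMNS)
    df["artifact_flag"] = df["artifact_flag"].astype(bool)
    if (df["snr"] <= 0).any():
        raise TableSchemaError(f"{path}: snr must be > 0")
    if (df["fd"] < 0).any():
        raise TableSchemaError(f"{path}: fd must be >= 0")
    return df


def _write_table(df: pd.DataFrame, path: str | Path, schema: dict[str, type]) -> None:
    df = df.copy()
    for col, typ in schema.items():
        if typ is bool:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(bool(v)))
        elif typ is float:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, sep="\t", index=False)


def write_draw_trials(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df[list(DRAW_COLUMNS)], path, DRAW_COLUMNS)


def write_recognition_trials(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df[list(RECOGNITION_COLUMNS)], path, RECOGNITION_COLUMNS)


def write_qc_table(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df[list(QC_COLUMNS)], path, QC_COLUMNS)


# ---------------------------------------------------------------------------
# Result reports


def _jsonify(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if obj is None or isinstance(obj, str):
        return obj
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    raise TypeError(f"cannot serialize {type(obj)}")


def report_json(result_objects) -> str:
    """Deterministic JSON serialization: sorted keys, version field, repr floats."""
    doc = {"schema_version": REPORT_SCHEMA_VERSION, "results": _jsonify(result_objects)}
    return json.dumps(doc, sort_keys=True, indent=1, allow_nan=False)


def write_report(result_objects, path: str | Path) -> None:
    Path(path).write_text(report_json(result_objects) + "\n")
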