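"""Point-cloud input/output, normalization and resampling.

Clouds are plain ``LabeledCloud`` records: an ``(M, 3)`` float64 coordinate
array plus a length-``M`` integer label vector.  Labels follow the fixed
public contract ``1 = non-ear``, ``2 = ear``; ``0`` is the "unlabeled"
sentinel used when a file carries no label source.

Two on-disk formats are supported:

* PLY (vertex-only dialect): ``x, y, z`` plus an optional integer scalar
  vertex property named ``label``.  ASCII and binary_little_endian files are
  read; files are always written as ASCII with 32-bit coordinates, hence the
  1e-6 round-trip tolerance on coordinates.
* XYZ text: whitespace-delimited, ``#`` comments ignored, 3 or 4 columns
  (the 4th column is the label).  A sidecar file ``<stem>.seg`` with one
  integer per line is read when present and no 4th column exists.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

UNLABELED = 0
NON_EAR = 1
EAR = 2

__all__ = [
    "LabeledCloud",
    "NormalizationRecord",
    "UNLABELED",
    "NON_EAR",
    "EAR",
    "read_labeled_cloud",
    "write_labeled_cloud",
    "normalize",
    "denormalize",
    "resample_to_count",
]


class CloudParseError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


@dataclass
class LabeledCloud:
    """A point set ``P = {p_1..p_M}`` with per-point labels ``Γ``."""

    coords: np.ndarray
    labels: np.ndarray
    id: str = "cloud"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (M, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("cloud must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.coords.shape[0],):
            raise ValueError(
                f"label count {self.labels.shape} does not match M={self.coords.shape[0]}"
            )
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0 (0 is the unlabeled sentinel)")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def is_labeled(self) -> bool:
        return bool(np.all(self.labels != UNLABELED))

    @classmethod
    def unlabeled(cls, coords: np.ndarray, id: str = "cloud") -> "LabeledCloud":
        coords = np.asarray(coords, dtype=np.float64)
        return cls(coords, np.full(coords.shape[0], UNLABELED, dtype=np.int64), id)


@dataclass
class NormalizationRecord:
    """Invertible record of the centroid-center + unit-sphere scaling."""

    centroid_shift: np.ndarray
    scale_factor: float

    def __post_init__(self) -> None:
        self.centroid_shift = np.asarray(self.centroid_shift, dtype=np.float64).reshape(3)
        self.scale_factor = float(self.scale_factor)
        if not self.scale_factor > 0:
            raise ValueError("scale_factor must be positive")

    def to_original(self, coords: np.ndarray) -> np.ndarray:
        """Map normalized coordinates back to the original frame."""
        return np.asarray(coords, dtype=np.float64) * self.scale_factor + self.centroid_shift

    def length_to_original(self, length: float) -> float:
        """Map a length measured in normalized units to original units."""
        return float(length) * self.scale_factor


def normalize(cloud: LabeledCloud) -> tuple[LabeledCloud, NormalizationRecord]:
    """Center the cloud at its centroid and scale it into the unit sphere.

    The returned record inverts the transform exactly (to float64 round-off),
    so phenotype lengths can be reported in the original units.  A degenerate
    cloud (all points coincident) is centered with ``scale_factor = 1``.
    """
    centroid = cloud.coords.mean(axis=0)
    shifted = cloud.coords - centroid
    radius = float(np.linalg.norm(shifted, axis=1).max())
    scale = radius if radius > 0 else 1.0
    out = LabeledCloud(shifted / scale, cloud.labels.copy(), cloud.id)
    return out, NormalizationRecord(centroid, scale)


def denormalize(cloud: LabeledCloud, record: NormalizationRecord) -> LabeledCloud:
    """Inverse of :func:`normalize`."""
    return LabeledCloud(record.to_original(cloud.coords), cloud.labels.copy(), cloud.id)


def resample_to_count(cloud: LabeledCloud, m_target: int, seed: int) -> LabeledCloud:
    """Return a cloud with exactly ``m_target`` points.

    Downsampling draws without replacement; upsampling draws with
    replacement.  Labels travel with their points.  Bit-reproducible for a
    fixed seed.
    """
    if m_target < 1:
        raise ValueError("m_target must be >= 1")
    rng = np.random.default_rng(seed)
    m = cloud.n_points
    if m_target <= m:
        idx = rng.choice(m, size=m_target, replace=False)
    else:
        idx = rng.choice(m, size=m_target, replace=True)
    return LabeledCloud(cloud.coords[idx], cloud.labels[idx], cloud.id)


# ---------------------------------------------------------------------------
# PLY


_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> LabeledCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudParseError(f"{path}: not a PLY file (missing 'ply' magic)")
        fmt = None
        n_vertices = None
        properties: list[tuple[str, str]] = []
        in_vertex = False
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise CloudParseError(f"{path}: unexpected EOF in header at line {lineno}")
            tokens = raw.decode("ascii", errors="replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tokens[2])
                elif int(tokens[2]) > 0:
                    raise CloudParseError(
                        f"{path}: unsupported non-empty element '{tokens[1]}' (vertex-only dialect)"
                    )
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise CloudParseError(f"{path}: list properties are not supported")
                if tokens[1] not in _PLY_DTYPES:
                    raise CloudParseError(f"{path}: unknown property type '{tokens[1]}' at line {lineno}")
                properties.append((tokens[2], _PLY_DTYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudParseError(f"{path}: unsupported PLY format '{fmt}'")
        if n_vertices is None:
            raise CloudParseError(f"{path}: no vertex element")
        names = [p[0] for p in properties]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise CloudParseError(f"{path}: missing vertex property '{axis}'")
        if fmt == "ascii":
            rows = []
            for i in range(n_vertices):
                raw = fh.readline()
                lineno += 1
                fields = raw.split()
                if len(fields) != len(properties):
                    raise CloudParseError(
                        f"{path}: line {lineno}: expected {len(properties)} fields, got {len(fields)}"
                    )
                rows.append([float(v) for v in fields])
            data = np.asarray(rows, dtype=np.float64)
            if data.size == 0:
                data = data.reshape(0, len(properties))
        else:
            dtype = np.dtype([(n, "<" + t) for n, t in properties])
            buf = fh.read(dtype.itemsize * n_vertices)
            if len(buf) < dtype.itemsize * n_vertices:
                raise CloudParseError(f"{path}: truncated binary vertex data")
            rec = np.frombuffer(buf, dtype=dtype, count=n_vertices)
            data = np.column_stack([rec[n].astype(np.float64) for n in names])
    coords = data[:, [names.index("x"), names.index("y"), names.index("z")]]
    if "label" in names:
        labels = data[:, names.index("label")].astype(np.int64)
    else:
        labels = np.full(n_vertices, UNLABELED, dtype=np.int64)
    return LabeledCloud(coords, labels, Path(path).stem)


def _write_ply(cloud: LabeledCloud, path: Path) -> None:
    write_labels = cloud.labels is not None and np.any(cloud.labels != UNLABELED)
    header = ["ply", "format ascii 1.0", f"element vertex {cloud.n_points}",
              "property float x", "property float y", "property float z"]
    if write_labels:
        header.append("property int label")
    header.append("end_header")
    coords32 = cloud.coords.astype(np.float32)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i in range(cloud.n_points):
            x, y, z = coords32[i]
            if write_labels:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g} {int(cloud.labels[i])}\n")
            else:
                fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")


# ---------------------------------------------------------------------------
# XYZ text


def _read_xyz(path: Path) -> LabeledCloud:
    rows = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) not in (3, 4):
                raise CloudParseError(f"{path}: line {lineno}: expected 3 or 4 columns, got {len(fields)}")
            if n_cols is None:
                n_cols = len(fields)
            elif len(fields) != n_cols:
                raise CloudParseError(f"{path}: line {lineno}: inconsistent column count")
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise CloudParseError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise CloudParseError(f"{path}: no points")
    data = np.asarray(rows, dtype=np.float64)
    coords = data[:, :3]
    if n_cols == 4:
        labels = data[:, 3].astype(np.int64)
    else:
        sidecar = path.with_suffix(".seg")
        if sidecar.exists():
            labels = np.loadtxt(sidecar, dtype=np.int64, ndmin=1)
            if labels.shape[0] != coords.shape[0]:
                raise CloudParseError(
                    f"{sidecar}: {labels.shape[0]} labels for {coords.shape[0]} points"
                )
        else:
            labels = np.full(coords.shape[0], UNLABELED, dtype=np.int64)
    return LabeledCloud(coords, labels, path.stem)


def _write_xyz(cloud: LabeledCloud, path: Path) -> None:
    write_labels = np.any(cloud.labels != UNLABELED)
    with open(path, "w") as fh:
        for i in range(cloud.n_points):
            x, y, z = cloud.coords[i]
            if write_labels:
                fh.write(f"{x:.9f} {y:.9f} {z:.9f} {int(cloud.labels[i])}\n")
            else:
                fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")


def _detect_format(path: Path, format_hint: str) -> str:
    if format_hint in ("ply", "xyz"):
        return format_hint
    if format_hint != "auto":
        raise ValueError(f"unknown format hint '{format_hint}'")
    suffix = path.suffix.lower()
    if suffix == ".ply":
        return "ply"
    if suffix in (".xyz", ".txt", ".pts"):
        return "xyz"
    with open(path, "rb") as fh:
        return "ply" if fh.read(3) == b"ply" else "xyz"


def read_labeled_cloud(path, format_hint: str = "auto") -> LabeledCloud:
    """Read a cloud from PLY or XYZ text; labels default to the sentinel."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    return _read_ply(path) if fmt == "ply" else _read_xyz(path)


def write_labeled_cloud(cloud: LabeledCloud, path, format: str = "auto") -> Path:
    """Write a cloud as ASCII PLY or XYZ text, parseable by ``read_labeled_cloud``."""
    path = Path(path)
    if format == "auto":
        fmt = "ply" if path.suffix.lower() == ".ply" else "xyz"
    elif format in ("ply", "xyz"):
        fmt = format
    else:
        raise ValueError(f"unknown format '{format}'")
    if fmt == "ply":
        _write_ply(cloud, path)
    else:
        _write_xyz(cloud, path)
    return path
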