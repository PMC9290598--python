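"""Point cloud container and readers/writers (LAS 1.2, PLY, XYZ CSV).

Photogrammetric vegetation surveys deliver dense point clouds in a planar
metric CRS (typically UTM).  This module holds them as flat numpy arrays and
speaks the three interchange formats the pipeline accepts.  Points carried as
classified noise (plot infrastructure such as marker flags; LAS classes 7 and
18) are flagged on load and excluded from every downstream computation.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PointCloud", "load_point_cloud", "write_point_cloud"]

# LAS classification codes mapped to the noise flag
_LAS_NOISE_CLASSES = (7, 18)

_LAS_HEADER_SIZE = 227  # LAS 1.2, no VLRs
_LAS_POINT0_DTYPE = np.dtype(
    [
        ("X", "<i4"),
        ("Y", "<i4"),
        ("Z", "<i4"),
        ("intensity", "<u2"),
        ("flags", "u1"),
        ("classification", "u1"),
        ("scan_angle", "i1"),
        ("user_data", "u1"),
        ("point_source", "<u2"),
    ]
)


@dataclass
class PointCloud:
    """Georeferenced 3-D points with a per-point noise flag.

    Parameters
    ----------
    xyz : (n, 3) float64 array
        Coordinates in metres, planar metric CRS.
    noise : (n,) bool array
        True for points classified as noise (excluded downstream).
    """

    xyz: np.ndarray
    noise: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        if self.noise is None:
            self.noise = np.zeros(len(self.xyz), dtype=bool)
        else:
            self.noise = np.asarray(self.noise, dtype=bool).reshape(-1)
        if len(self.noise) != len(self.xyz):
            raise ValueError("noise flag length does not match point count")
        if not np.isfinite(self.xyz).all():
            bad = int(np.flatnonzero(~np.isfinite(self.xyz).all(axis=1))[0])
            raise ValueError(f"non-finite coordinate at point index {bad}")

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def clean(self) -> "PointCloud":
        """Return a copy with noise-flagged points dropped."""
        keep = ~self.noise
        return PointCloud(self.xyz[keep], np.zeros(keep.sum(), dtype=bool))

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.xyz[mask], self.noise[mask])


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".las"}:
        return "las"
    if suffix in {".laz"}:
        return "laz"
    if suffix in {".ply"}:
        return "ply"
    if suffix in {".csv", ".txt", ".xyz"}:
        return "csv_xyz"
    raise ValueError(f"cannot infer point-cloud format from suffix {suffix!r}")


def load_point_cloud(path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud from LAS 1.2, PLY or headered x,y,z[,noise] CSV.

    LAS classifications 7 (low noise) and 18 (high noise) set the noise flag.
    LAZ is not supported: decompress externally and pass the LAS.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"point cloud file not found: {path}")
    fmt = fmt or _sniff_format(path)
    if fmt == "las":
        return _read_las(path)
    if fmt == "laz":
        raise IOError(
            "LAZ (compressed LAS) is not supported; decompress to .las first"
        )
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "csv_xyz":
        return _read_csv(path)
    raise ValueError(f"unknown point-cloud format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path, fmt: str | None = None,
                      binary: bool = True) -> None:
    """Write a point cloud; format inferred from the suffix unless given."""
    path = Path(path)
    fmt = fmt or _sniff_format(path)
    if fmt == "las":
        _write_las(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt == "csv_xyz":
        _write_csv(cloud, path)
    else:
        raise ValueError(f"unknown point-cloud format {fmt!r}")


# ---------------------------------------------------------------- CSV

def _read_csv(path: Path) -> PointCloud:
    df = pd.read_csv(path, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in ("x", "y", "z") if c not in cols]
    if missing:
        raise ValueError(f"CSV {path} lacks required columns: {missing}")
    xyz = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=np.float64)
    if not np.isfinite(xyz).all():
        bad = int(np.flatnonzero(~np.isfinite(xyz).all(axis=1))[0])
        raise ValueError(f"non-finite coordinate in {path} at row {bad}")
    noise = None
    if "noise" in cols:
        noise = df[cols["noise"]].to_numpy().astype(bool)
    return PointCloud(xyz, noise)


def _write_csv(cloud: PointCloud, path: Path) -> None:
    df = pd.DataFrame(
        {"x": cloud.x, "y": cloud.y, "z": cloud.z,
         "noise": cloud.noise.astype(int)}
    )
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------- LAS 1.2

def _las_scale(extent: float) -> float:
    # keep scaled int32 in range with headroom; floor gives <=1e-7 m error
    return max(1e-7, extent / (2**31 / 1.25))


def _read_las(path: Path) -> PointCloud:
    raw = path.read_bytes()
    if raw[:4] != b"LASF":
        raise IOError(f"{path} is not a LAS file (bad signature)")
    header_size, = struct.unpack_from("<H", raw, 94)
    offset_to_points, = struct.unpack_from("<I", raw, 96)
    point_format, = struct.unpack_from("<B", raw, 104)
    record_len, = struct.unpack_from("<H", raw, 105)
    n_points, = struct.unpack_from("<I", raw, 107)
    scales = struct.unpack_from("<3d", raw, 131)
    offsets = struct.unpack_from("<3d", raw, 155)
    if point_format not in (0, 1):
        raise IOError(f"unsupported LAS point format {point_format}")
    body = raw[offset_to_points:offset_to_points + n_points * record_len]
    rec = np.frombuffer(body, dtype=np.uint8).reshape(n_points, record_len)
    pts = rec[:, : _LAS_POINT0_DTYPE.itemsize].copy().view(_LAS_POINT0_DTYPE)
    pts = pts.reshape(n_points)
    xyz = np.empty((n_points, 3))
    for k, name in enumerate(("X", "Y", "Z")):
        xyz[:, k] = pts[name] * scales[k] + offsets[k]
    classification = pts["classification"] & 0x1F
    noise = np.isin(classification, _LAS_NOISE_CLASSES)
    return PointCloud(xyz, noise)


def _write_las(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    if n == 0:
        raise ValueError("refusing to write an empty LAS file")
    mins = cloud.xyz.min(axis=0)
    maxs = cloud.xyz.max(axis=0)
    scales = np.array([_las_scale(e) for e in (maxs - mins)])
    pts = np.zeros(n, dtype=_LAS_POINT0_DTYPE)
    for k, name in enumerate(("X", "Y", "Z")):
        pts[name] = np.round((cloud.xyz[:, k] - mins[k]) / scales[k]).astype(
            np.int64
        )
    pts["classification"] = np.where(cloud.noise, 7, 0).astype(np.uint8)
    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    struct.pack_into("<BB", header, 24, 1, 2)  # version 1.2
    struct.pack_into("<32s", header, 26, b"canopymass")
    struct.pack_into("<32s", header, 58, b"canopymass")
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)
    struct.pack_into("<B", header, 104, 0)
    struct.pack_into("<H", header, 105, _LAS_POINT0_DTYPE.itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<I", header, 111, n)  # points by return, return 1
    struct.pack_into("<3d", header, 131, *scales)
    struct.pack_into("<3d", header, 155, *mins)
    struct.pack_into(
        "<6d", header, 179,
        maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2],
    )
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(pts.tobytes())


# ---------------------------------------------------------------- PLY

_PLY_PROPS = [("x", "<f8"), ("y", "<f8"), ("z", "<f8"), ("noise", "u1")]


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise IOError(f"{path} is not a PLY file")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise IOError(f"{path}: unexpected end of PLY header")
            tokens = line.decode("ascii").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        type_map = {
            "float": "<f4", "float32": "<f4", "double": "<f8",
            "float64": "<f8", "uchar": "u1", "uint8": "u1", "char": "i1",
            "int": "<i4", "int32": "<i4", "uint": "<u4", "short": "<i2",
            "ushort": "<u2",
        }
        dtype = np.dtype([(name, type_map[t]) for name, t in props])
        if fmt == "ascii":
            data = np.loadtxt(fh, dtype=dtype, max_rows=n_vertex, ndmin=1)
        elif fmt == "binary_little_endian":
            data = np.frombuffer(
                fh.read(n_vertex * dtype.itemsize), dtype=dtype
            )
        else:
            raise IOError(f"unsupported PLY format {fmt!r}")
    names = dtype.names or ()
    for c in ("x", "y", "z"):
        if c not in names:
            raise IOError(f"{path}: PLY vertex element lacks property {c!r}")
    xyz = np.column_stack(
        [data["x"], data["y"], data["z"]]
    ).astype(np.float64)
    noise = data["noise"].astype(bool) if "noise" in names else None
    return PointCloud(xyz, noise)


def _write_ply(cloud: PointCloud, path: Path, binary: bool = True) -> None:
    n = len(cloud)
    fmt = "binary_little_endian" if binary else "ascii"
    header = "\n".join(
        ["ply", f"format {fmt} 1.0", f"element vertex {n}"]
        + [
            f"property {ptype} {name}"
            for name, ptype in (
                ("x", "double"), ("y", "double"), ("z", "double"),
                ("noise", "uchar"),
            )
        ]
        + ["end_header", ""]
    )
    rec = np.zeros(n, dtype=np.dtype(_PLY_PROPS))
    rec["x"], rec["y"], rec["z"] = cloud.x, cloud.y, cloud.z
    rec["noise"] = cloud.noise.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            np.savetxt(fh, np.column_stack(
                [cloud.x, cloud.y, cloud.z, cloud.noise.astype(int)]
            ), fmt=["%.9f", "%.9f", "%.9f", "%d"])
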