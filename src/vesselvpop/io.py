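"""Reading and writing centerline populations.

A centerline is an ordered 3D polyline with a per-point inner radius, in
millimetres, stored one point per row in a small CSV dialect
(``x_mm,y_mm,z_mm,r_mm[,flag]``).  Populations are grouped by a JSON manifest
that lists per-artery files together with an anatomical label (``BA``,
``L_ICA``, ``R_ICA`` or free text).  A write-only legacy-VTK polyline export
is provided for visualization.

Coordinates live in a fixed laboratory frame; any registration of the source
images to a common atlas is treated as an upstream concern.  Duplicate
consecutive points are merged at load time (averaging their radii) because
downstream discrete curvature divides by the cubed segment length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError

logger = logging.getLogger(__name__)

CSV_COLUMNS = ("x_mm", "y_mm", "z_mm", "r_mm")
FLAG_COLUMN = "flag"


@dataclass
class Centerline:
    """An ordered vessel centerline with per-point inner radius (mm).

    Parameters
    ----------
    points
        ``(n, 3)`` array of (x, y, z) positions in mm, ordered
        proximal-to-distal.
    radii
        ``(n,)`` array of inner radii in mm.
    label
        Artery class tag (``BA``, ``L_ICA``, ``R_ICA`` or free text).
    id
        Identifier of this artery within its population.
    sampled
        True when the record was drawn from a statistical model rather than
        observed; only then are negative radii permitted (they are a known,
        reported property of Gaussian sampling and are never silently fixed).
    """

    points: np.ndarray
    radii: np.ndarray
    label: str = ""
    id: str = ""
    sampled: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise FormatError(f"points must be (n, 3), got {self.points.shape}")
        n = self.points.shape[0]
        if self.radii.shape != (n,):
            raise FormatError(
                f"radii length {self.radii.shape} does not match {n} points"
            )
        if n < 2:
            raise DegenerateInputError(
                f"centerline {self.id!r}: need at least 2 distinct points, got {n}"
            )
        if not np.isfinite(self.points).all() or not np.isfinite(self.radii).all():
            raise FormatError(f"centerline {self.id!r}: non-finite coordinate or radius")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise FormatError(
                f"centerline {self.id!r}: zero-length segment (duplicate consecutive points)"
            )
        if not self.sampled and np.any(self.radii < 0):
            raise FormatError(
                f"centerline {self.id!r}: negative radius in a non-sampled record"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, Centerline):
            return NotImplemented
        return (
            np.array_equal(self.points, other.points)
            and np.array_equal(self.radii, other.radii)
            and self.label == other.label
            and self.id == other.id
            and self.sampled == other.sampled
        )


@dataclass
class ManifestEntry:
    id: str
    path: str
    label: str = ""


@dataclass
class PopulationManifest:
    """A list of centerline files constituting one population (units fixed to mm)."""

    entries: list[ManifestEntry]
    units: str = "mm"
    metadata: dict = field(default_factory=dict)
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        if self.units != "mm":
            raise FormatError(f"unsupported units {self.units!r}; only 'mm' is defined")
        ids = [e.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate manifest ids: {dupes}")

    def resolve(self, entry: ManifestEntry) -> Path:
        p = Path(entry.path)
        return p if p.is_absolute() else self.base_dir / p


def _merge_duplicate_points(
    pts: np.ndarray, radii: np.ndarray, origin: str
) -> tuple[np.ndarray, np.ndarray]:
    """Merge runs of identical consecutive points, averaging their radii."""
    same = np.all(pts[1:] == pts[:-1], axis=1)
    if not same.any():
        return pts, radii
    # group index increments whenever the point changes
    group = np.concatenate([[0], np.cumsum(~same)])
    n_groups = group[-1] + 1
    out_pts = np.empty((n_groups, 3))
    out_r = np.empty(n_groups)
    for g in range(n_groups):
        sel = group == g
        out_pts[g] = pts[sel][0]
        out_r[g] = radii[sel].mean()
    logger.warning(
        "%s: merged %d duplicate consecutive point(s), radii averaged",
        origin,
        int(same.sum()),
    )
    return out_pts, out_r


def read_centerline(path: str | Path, id: str = "", label: str = "") -> Centerline:
    """Read one centerline CSV (columns ``x_mm,y_mm,z_mm,r_mm[,flag]``).

    Duplicate consecutive points are merged (radii averaged) with a logged
    warning.  A ``flag`` column marks the record as model-sampled.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; header must be "
                          f"{','.join(CSV_COLUMNS)}[,{FLAG_COLUMN}]")
    numeric = {}
    for col in CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise FormatError(f"{path}: empty cell in column {col!r}, data row {row + 1}")
        numeric[col] = coerced.to_numpy(dtype=float)
    pts = np.column_stack([numeric["x_mm"], numeric["y_mm"], numeric["z_mm"]])
    radii = numeric["r_mm"]
    if pts.shape[0] == 0:
        raise DegenerateInputError(f"{path}: empty centerline file")
    pts, radii = _merge_duplicate_points(pts, radii, str(path))
    if pts.shape[0] < 2:
        raise DegenerateInputError(
            f"{path}: fewer than 2 distinct points after deduplication"
        )
    sampled = FLAG_COLUMN in df.columns
    return Centerline(points=pts, radii=radii, id=id or path.stem, label=label,
                      sampled=sampled)


def write_centerline(c: Centerline, path: str | Path) -> Path:
    """Write a centerline CSV; the round trip preserves values to <1e-9 mm.

    Model-sampled records get a ``flag`` column (1 where the radius is
    negative) so the permissive radius rule survives the round trip.
    """
    path = Path(path)
    data = {
        "x_mm": c.points[:, 0],
        "y_mm": c.points[:, 1],
        "z_mm": c.points[:, 2],
        "r_mm": c.radii,
    }
    if c.sampled:
        data[FLAG_COLUMN] = (c.radii < 0).astype(int)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


def read_manifest(path: str | Path) -> PopulationManifest:
    """Read a population manifest (JSON); relative paths resolve next to it."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if "entries" not in obj:
        raise FormatError(f"{path}: manifest lacks 'entries'")
    entries = [
        ManifestEntry(id=str(e["id"]), path=str(e["path"]), label=str(e.get("label", "")))
        for e in obj["entries"]
    ]
    manifest = PopulationManifest(
        entries=entries,
        units=obj.get("units", "mm"),
        metadata=obj.get("metadata", {}),
        base_dir=path.parent,
    )
    for entry in manifest.entries:
        if not manifest.resolve(entry).exists():
            raise FormatError(
                f"{path}: entry {entry.id!r} references missing file {entry.path!r}"
            )
    return manifest


def write_manifest(manifest: PopulationManifest, path: str | Path) -> Path:
    path = Path(path)
    obj = {
        "units": manifest.units,
        "entries": [
            {"id": e.id, "path": e.path, "label": e.label} for e in manifest.entries
        ],
        "metadata": manifest.metadata,
    }
    path.write_text(json.dumps(obj, indent=2) + "\n", encoding="utf-8")
    return path


def read_population(manifest: PopulationManifest) -> list[Centerline]:
    """Read every centerline named by the manifest, in manifest order."""
    out: list[Centerline] = []
    for entry in manifest.entries:
        try:
            out.append(read_centerline(manifest.resolve(entry), id=entry.id,
                                        label=entry.label))
        except Exception as exc:
            raise FormatError(f"manifest entry {entry.id!r}: {exc}") from exc
    return out


def write_population(
    centerlines: Sequence[Centerline],
    directory: str | Path,
    manifest_name: str = "manifest.json",
    metadata: Mapping | None = None,
) -> Path:
    """Write one CSV per centerline plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, c in enumerate(centerlines):
        cid = c.id or f"artery_{i:03d}"
        fname = f"{cid}.csv"
        write_centerline(c, directory / fname)
        entries.append(ManifestEntry(id=cid, path=fname, label=c.label))
    manifest = PopulationManifest(entries=entries, metadata=dict(metadata or {}),
                                  base_dir=directory)
    return write_manifest(manifest, directory / manifest_name)


def write_vtk_polyline(c: Centerline, path: str | Path) -> Path:
    """Export a centerline as a legacy-ASCII VTK polyline with radius point data.

    Write-only convenience for viewers such as ParaView; never read back.
    """
    path = Path(path)
    n = c.n_points
    lines = [
        "# vtk DataFile Version 3.0",
        f"vessel centerline {c.id}",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in c.points]
    lines.append(f"LINES 1 {n + 1}")
    lines.append(" ".join([str(n)] + [str(i) for i in range(n)]))
    lines.append(f"POINT_DATA {n}")
    lines.append("SCALARS radius_mm double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{r:.17g}" for r in c.radii]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
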