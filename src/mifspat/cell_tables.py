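"""Canonical per-cell tables: read, validate, write, and coordinate-based marker merging.

The pipeline consumes segmented per-cell tables (one row per cell) exported by
image-analysis software after spectral unmixing and cell segmentation.  The
canonical dialect is a UTF-8 CSV with header

    sample_id,roi_id,timepoint,cell_id,x_um,y_um,<marker1>,<marker2>,...

one file may hold many regions of interest (ROIs).  Coordinates are continuous
micron positions in image convention: origin at the ROI top-left, y increasing
downward.  Marker columns are boolean positivity calls; the reader tolerates
the synonym encodings commonly found in vendor exports (``pos``/``neg``,
``+``/``-``, ``TRUE``/``FALSE``).

Vendor exports frequently ship one table per marker.  ``merge_marker_tables``
reconstructs the per-cell co-expression map by joining tables on cell
coordinates rounded to 0.1 µm, the same x/y-based merge used to combine
single-marker segmentations into phenotypes.  Cells missing from any input
are never silently discarded: the merge report tallies every drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CellTableFormatError,
    MergeAmbiguityError,
    MergeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Default ROI field size of the scanner capture, microns.
DEFAULT_ROI_WIDTH_UM = 931.0
DEFAULT_ROI_HEIGHT_UM = 698.0

BASE_COLUMNS = ["sample_id", "roi_id", "timepoint", "cell_id", "x_um", "y_um"]

# Tolerant header synonyms (lower-cased, stripped) -> canonical column.
_HEADER_SYNONYMS = {
    "sample_id": "sample_id",
    "sample": "sample_id",
    "sample name": "sample_id",
    "roi_id": "roi_id",
    "roi": "roi_id",
    "annotation id": "roi_id",
    "region": "roi_id",
    "timepoint": "timepoint",
    "time point": "timepoint",
    "week": "timepoint",
    "cell_id": "cell_id",
    "cell id": "cell_id",
    "x_um": "x_um",
    "x": "x_um",
    "cell x position": "x_um",
    "y_um": "y_um",
    "y": "y_um",
    "cell y position": "y_um",
}

_TRUTHY = {"1", "1.0", "pos", "positive", "+", "true", "yes"}
_FALSY = {"0", "0.0", "neg", "negative", "-", "−", "false", "no"}


@dataclass
class CellRecord:
    """One segmented cell: identity, micron position, and marker positivity map."""

    cell_id: str
    sample_id: str
    roi_id: str
    timepoint: str
    x: float
    y: float
    markers: dict[str, bool]


@dataclass
class ROIFrame:
    """All cells of one (sample, ROI, timepoint) capture.

    ``cells`` is a DataFrame with columns ``cell_id, x_um, y_um`` plus one
    boolean column per marker.  ``width``/``height`` are the field size in
    microns; ``area_mm2`` is the normalisation denominator for densities.
    """

    sample_id: str
    roi_id: str
    timepoint: str
    width: float = DEFAULT_ROI_WIDTH_UM
    height: float = DEFAULT_ROI_HEIGHT_UM
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
    meta: dict = field(default_factory=dict)

    @property
    def area_mm2(self) -> float:
        return self.width * self.height / 1e6

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def marker_names(self) -> list[str]:
        return [c for c in self.cells.columns if c not in ("cell_id", "x_um", "y_um")]

    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.roi_id, self.timepoint)

    def xy(self) -> np.ndarray:
        """(n, 2) array of cell positions in microns."""
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)

    def records(self) -> list[CellRecord]:
        markers = self.marker_names
        out = []
        for d in self.cells.to_dict("records"):
            out.append(
                CellRecord(
                    cell_id=d["cell_id"],
                    sample_id=self.sample_id,
                    roi_id=self.roi_id,
                    timepoint=self.timepoint,
                    x=float(d["x_um"]),
                    y=float(d["y_um"]),
                    markers={m: bool(d[m]) for m in markers},
                )
            )
        return out


def validate_frame(frame: ROIFrame, required_markers: Iterable[str] | None = None) -> None:
    """Check frame invariants; raise :class:`ValidationError` on the first violation.

    Invariants: positive area, unique cell ids, coordinates within
    ``[0, width] x [0, height]``, and (when ``required_markers`` is given,
    e.g. from a panel) presence of every declared marker column.
    """
    if frame.width <= 0 or frame.height <= 0:
        raise ValidationError(
            f"frame {frame.key()}: non-positive ROI dimensions {frame.width}x{frame.height}"
        )
    df = frame.cells
    for col in ("cell_id", "x_um", "y_um"):
        if col not in df.columns:
            raise ValidationError(f"frame {frame.key()}: missing column {col!r}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"frame {frame.key()}: duplicate cell_id {dup!r}")
    x = df["x_um"].to_numpy(dtype=float)
    y = df["y_um"].to_numpy(dtype=float)
    if len(x) and (
        np.nanmin(x) < 0
        or np.nanmax(x) > frame.width
        or np.nanmin(y) < 0
        or np.nanmax(y) > frame.height
    ):
        raise ValidationError(
            f"frame {frame.key()}: coordinates outside the {frame.width}x{frame.height} um field"
        )
    if required_markers is not None:
        missing = [m for m in required_markers if m not in df.columns]
        if missing:
            raise ValidationError(f"frame {frame.key()}: missing marker columns {missing}")


def _parse_positivity(value, column: str, line: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise CellTableFormatError(
        f"line {line}: unparseable positivity value {value!r} in column {column!r}"
    )


def read_cell_table(
    path: str | Path,
    markers: Sequence[str] | None = None,
    *,
    width: float = DEFAULT_ROI_WIDTH_UM,
    height: float = DEFAULT_ROI_HEIGHT_UM,
    strict: bool = False,
) -> list[ROIFrame]:
    """Read a canonical (or synonym-headed) cell table into per-ROI frames.

    Parameters
    ----------
    path
        CSV file; may contain many (sample, ROI, timepoint) groups.
    markers
        Marker columns expected; defaults to every non-base column found.
        A declared marker missing from the header is a format error.
    width, height
        ROI field size in microns, used for bounds validation.
    strict
        If True, any rejected row raises instead of being dropped.

    Returns
    -------
    list of ROIFrame, grouped by (sample_id, roi_id, timepoint), each
    validated.  Rejected rows (non-numeric coordinates, unparseable
    positivity) are logged with their line number and reason.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    rename = {}
    for col in raw.columns:
        canon = _HEADER_SYNONYMS.get(col.strip().lower())
        if canon is not None:
            rename[col] = canon
    raw = raw.rename(columns=rename)

    missing = [c for c in BASE_COLUMNS if c not in raw.columns]
    if missing:
        raise CellTableFormatError(f"{path}: missing mandatory column(s) {missing}")

    found_markers = [c for c in raw.columns if c not in BASE_COLUMNS]
    if markers is None:
        markers = found_markers
    else:
        absent = [m for m in markers if m not in raw.columns]
        if absent:
            raise CellTableFormatError(f"{path}: missing marker column(s) {absent}")

    rows = []
    n_rejected = 0
    # dict-records iteration keeps non-identifier column names (PD-1, B7-H3) intact
    for i, d in enumerate(raw.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            x = float(d["x_um"])
            y = float(d["y_um"])
        except (TypeError, ValueError):
            msg = f"{path}:{line}: non-numeric coordinate ({d['x_um']!r}, {d['y_um']!r})"
            if strict:
                raise CellTableFormatError(msg)
            logger.warning("rejected row — %s", msg)
            n_rejected += 1
            continue
        try:
            calls = {m: _parse_positivity(d[m], m, line) for m in markers}
        except CellTableFormatError as exc:
            if strict:
                raise
            logger.warning("rejected row — %s: %s", path, exc)
            n_rejected += 1
            continue
        rows.append(
            {
                "sample_id": str(d["sample_id"]),
                "roi_id": str(d["roi_id"]),
                "timepoint": str(d["timepoint"]),
                "cell_id": str(d["cell_id"]),
                "x_um": x,
                "y_um": y,
                **calls,
            }
        )
    if n_rejected:
        logger.warning("%s: rejected %d of %d rows", path, n_rejected, len(raw))

    frames: list[ROIFrame] = []
    if not rows:
        return frames
    df = pd.DataFrame(rows)
    for m in markers:
        df[m] = df[m].astype(bool)
    for (sample, roi, tp), grp in df.groupby(
        ["sample_id", "roi_id", "timepoint"], sort=True
    ):
        cells = grp[["cell_id", "x_um", "y_um", *markers]].reset_index(drop=True)
        frame = ROIFrame(sample, roi, tp, width=width, height=height, cells=cells)
        validate_frame(frame, required_markers=markers)
        frames.append(frame)
    return frames


def write_cell_table(frames: Sequence[ROIFrame], path: str | Path) -> None:
    """Write frames to one canonical CSV; inverse of :func:`read_cell_table`.

    All frames must share the same marker columns.  An empty frame list
    produces a header-only file with the base columns.
    """
    path = Path(path)
    if not frames:
        pd.DataFrame(columns=BASE_COLUMNS).to_csv(path, index=False)
        return
    markers = frames[0].marker_names
    for f in frames[1:]:
        if f.marker_names != markers:
            raise ValidationError(
                f"frame {f.key()}: marker columns {f.marker_names} differ from {markers}"
            )
    parts = []
    for f in frames:
        validate_frame(f, required_markers=markers)
        part = f.cells.copy()
        part.insert(0, "sample_id", f.sample_id)
        part.insert(1, "roi_id", f.roi_id)
        part.insert(2, "timepoint", f.timepoint)
        parts.append(part[BASE_COLUMNS + markers])
    out = pd.concat(parts, ignore_index=True)
    out[markers] = out[markers].astype(int)
    out.to_csv(path, index=False)


def _round_key(x: float, y: float, decimals: int = 1) -> tuple[float, float]:
    # -0.0 normalised so 0.04 and -0.04 round to the same key
    rx = round(float(x), decimals) + 0.0
    ry = round(float(y), decimals) + 0.0
    return (rx, ry)


def merge_marker_tables(
    tables: Sequence[Sequence[ROIFrame]],
    tol: float = 0.1,
    labels: Sequence[str] | None = None,
) -> tuple[list[ROIFrame], dict[str, dict[str, int]]]:
    """Merge single-marker per-cell tables on rounded x/y coordinates.

    Each element of ``tables`` is the frame set from one single-marker export;
    every frame must carry exactly one marker column.  Cells are matched when
    their coordinates, rounded to one decimal (0.1 µm), agree exactly across
    every input; matched cells receive the union marker map.  Cells absent
    from any input are dropped and tallied per input.  Two cells of one table
    colliding on the same rounded coordinate raise
    :class:`MergeAmbiguityError` rather than guessing.

    Returns ``(merged_frames, report)`` with
    ``report[label] = {"n_rows", "n_matched", "n_dropped"}``.
    The merge is order-independent: permuting ``tables`` yields identical
    merged frames (marker columns are sorted; merged cell ids derive from
    the rounded coordinates).
    """
    if tol > 0.1 + 1e-12:
        raise MergeError(f"tolerance {tol} exceeds the 0.1 um rounding grid")
    if not tables:
        raise MergeError("no input tables")
    if labels is None:
        labels = []
        for frames in tables:
            mk = frames[0].marker_names if frames else ["?"]
            labels.append(mk[0] if mk else "?")
    if len(labels) != len(tables):
        raise MergeError("labels length does not match tables")

    keysets = []
    for frames in tables:
        for f in frames:
            if len(f.marker_names) != 1:
                raise MergeError(
                    f"frame {f.key()}: expected exactly one marker column, got {f.marker_names}"
                )
        keysets.append({f.key() for f in frames})
    common = set.intersection(*keysets) if keysets else set()
    if not common:
        raise MergeError("no (sample, roi, timepoint) keys shared by all inputs")

    # per-input coordinate maps, checking for ambiguous collisions
    report = {
        lab: {"n_rows": 0, "n_matched": 0, "n_dropped": 0} for lab in labels
    }
    per_input: list[dict[tuple, dict[tuple, bool]]] = []
    geometry: dict[tuple, tuple[float, float]] = {}
    for lab, frames in zip(labels, tables):
        maps: dict[tuple, dict[tuple, bool]] = {}
        for f in frames:
            if f.key() not in common:
                report[lab]["n_rows"] += f.n_cells
                report[lab]["n_dropped"] += f.n_cells
                continue
            geometry[f.key()] = (f.width, f.height)
            marker = f.marker_names[0]
            cmap: dict[tuple, bool] = {}
            for cx, cy, val in zip(
                f.cells["x_um"], f.cells["y_um"], f.cells[marker]
            ):
                key = _round_key(cx, cy)
                if key in cmap:
                    raise MergeAmbiguityError(
                        f"frame {f.key()}, marker {marker}: two cells collide at "
                        f"rounded coordinate {key} (within tol {tol} um)"
                    )
                cmap[key] = bool(val)
            report[lab]["n_rows"] += f.n_cells
            maps[f.key()] = cmap
        per_input.append(maps)

    marker_of_input = [frames[0].marker_names[0] for frames in tables]
    marker_order = sorted(set(marker_of_input))
    merged: list[ROIFrame] = []
    for key in sorted(common):
        coord_sets = [set(maps.get(key, {})) for maps in per_input]
        shared = set.intersection(*coord_sets)
        for lab, cs in zip(labels, coord_sets):
            report[lab]["n_matched"] += len(shared)
            report[lab]["n_dropped"] += len(cs - shared)
        rows = []
        for (rx, ry) in sorted(shared):
            row = {
                "cell_id": f"m_{rx:.1f}_{ry:.1f}",
                "x_um": rx,
                "y_um": ry,
            }
            for maps, marker in zip(per_input, marker_of_input):
                row[marker] = maps[key][(rx, ry)]
            rows.append(row)
        width, height = geometry[key]
        cols = ["cell_id", "x_um", "y_um", *marker_order]
        cells = pd.DataFrame(rows, columns=cols)
        for m in marker_order:
            cells[m] = cells[m].astype(bool)
        merged.append(
            ROIFrame(key[0], key[1], key[2], width=width, height=height, cells=cells)
        )
    n_drop = sum(r["n_dropped"] for r in report.values())
    if n_drop:
        logger.warning("merge dropped %d unmatched cells across inputs", n_drop)
    return merged, report


def frames_by_key(frames: Iterable[ROIFrame]) -> Mapping[tuple[str, str, str], ROIFrame]:
    """Index frames by (sample_id, roi_id, timepoint)."""
    out: dict[tuple[str, str, str], ROIFrame] = {}
    for f in frames:
        if f.key() in out:
            raise ValidationError(f"duplicate frame key {f.key()}")
        out[f.key()] = f
    return out
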