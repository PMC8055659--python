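"""Nearest-neighbor proximity analysis between phenotype point sets.

For each reference cell (typically a CK+ malignant cell) the Euclidean
distance to the nearest cell of a target phenotype is computed within the
same ROI.  Per-pair medians pooled over the cohort feed a proximity matrix
(reference phenotypes × target phenotypes); the median of all pair medians
defines a global radius splitting phenotypes into *close* vs *far* relative
to the malignant compartment.

Distances are descriptive medians without edge correction: cells near the
ROI border have right-censored nearest-neighbor distances, which inflates
the upper tail but barely moves the median at the densities considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_tables import ROIFrame
from .errors import ParameterError
from .phenotyping import PanelSpec, phenotype_masks

logger = logging.getLogger(__name__)

CLOSE, FAR = "close", "far"


@dataclass
class DistanceSummary:
    """Per-cell nearest-neighbor distances from one reference to one target phenotype."""

    reference: str
    target: str
    nn_distances: np.ndarray
    n_ref: int
    n_target: int

    @property
    def median_distance(self) -> float:
        if len(self.nn_distances) == 0:
            return float("nan")
        return float(np.median(self.nn_distances))

    def proximity_label(self, radius: float) -> str:
        return classify_proximity(self.median_distance, radius)


def nn_distances(
    ref: np.ndarray,
    target: np.ndarray,
    ref_ids: Sequence | None = None,
    target_ids: Sequence | None = None,
) -> np.ndarray:
    """Euclidean distance from each reference point to its nearest target point.

    When ``ref_ids``/``target_ids`` are given and a reference cell is itself a
    member of the target set (overlapping phenotypes), its self-distance is
    excluded — the nearest *other* target cell counts.  A reference cell that
    is the only target cell is dropped with a warning.

    Raises :class:`ParameterError` if the target set is empty; an empty
    reference set yields an empty vector.
    """
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    if target.size == 0:
        raise ParameterError("no target cells")
    if ref.size == 0:
        return np.empty(0)

    shared = np.zeros(len(ref), dtype=bool)
    if ref_ids is not None and target_ids is not None:
        tset = set(target_ids)
        shared = np.array([i in tset for i in ref_ids], dtype=bool)

    tree = cKDTree(target)
    if not shared.any():
        d, _ = tree.query(ref, k=1)
        return np.asarray(d, dtype=float)

    k = min(2, len(target))
    d, idx = tree.query(ref, k=k)
    d = np.atleast_2d(d.reshape(len(ref), -1))
    idx = np.atleast_2d(idx.reshape(len(ref), -1))
    target_ids = list(target_ids)
    out = []
    for i in range(len(ref)):
        if not shared[i]:
            out.append(d[i, 0])
            continue
        # skip the neighbor that is this very cell
        for j in range(d.shape[1]):
            if target_ids[idx[i, j]] != list(ref_ids)[i]:
                out.append(d[i, j])
                break
        else:
            logger.warning(
                "reference cell %r is the only target cell; dropped", list(ref_ids)[i]
            )
    return np.asarray(out, dtype=float)


def summarize_pair(
    frames: Iterable[ROIFrame],
    panel: PanelSpec,
    reference: str,
    target: str,
) -> DistanceSummary:
    """Pool per-cell nearest-neighbor distances for one phenotype pair across frames.

    Distances are computed within each ROI (no cross-ROI stitching) and
    pooled over all frames.
    """
    dists = []
    n_ref = n_target = 0
    for f in frames:
        masks = phenotype_masks(f, panel)
        rmask, tmask = masks[reference], masks[target]
        n_ref += int(rmask.sum())
        n_target += int(tmask.sum())
        if not rmask.any() or not tmask.any():
            continue
        xy = f.xy()
        ids = f.cells["cell_id"].to_numpy()
        overlap = bool((rmask & tmask).any())
        dists.append(
            nn_distances(
                xy[rmask],
                xy[tmask],
                ref_ids=ids[rmask] if overlap else None,
                target_ids=ids[tmask] if overlap else None,
            )
        )
    pooled = np.concatenate(dists) if dists else np.empty(0)
    return DistanceSummary(
        reference=reference, target=target, nn_distances=pooled,
        n_ref=n_ref, n_target=n_target,
    )


def median_radius(summaries: Iterable[DistanceSummary], mode: str = "pair_medians") -> float:
    """Global close/far radius: the median over the per-pair median distances.

    ``mode="pooled_cells"`` pools every per-cell distance from all pairs
    before taking one median instead.
    """
    summaries = [s for s in summaries if len(s.nn_distances)]
    if not summaries:
        raise ParameterError("no distance summaries with defined medians")
    if mode == "pair_medians":
        return float(np.median([s.median_distance for s in summaries]))
    if mode == "pooled_cells":
        return float(np.median(np.concatenate([s.nn_distances for s in summaries])))
    raise ParameterError(f"unknown mode {mode!r}")


def classify_proximity(median_distance: float, radius: float) -> str:
    """*close* when the median distance is at or below the radius, else *far*."""
    if median_distance < 0 or radius < 0:
        raise ParameterError("distances must be non-negative")
    return CLOSE if median_distance <= radius else FAR


def proximity_matrix(
    frames: Sequence[ROIFrame],
    panel: PanelSpec,
    references: Sequence[str],
    targets: Sequence[str],
) -> pd.DataFrame:
    """Cohort-pooled median nearest-neighbor distance matrix (µm).

    Rows are reference phenotypes, columns target phenotypes; each entry
    pools per-cell distances across all frames then takes the median.  Pairs
    with no target cells anywhere are NaN and logged.
    """
    mat = pd.DataFrame(index=list(references), columns=list(targets), dtype=float)
    for ref in references:
        for tgt in targets:
            s = summarize_pair(frames, panel, ref, tgt)
            if len(s.nn_distances) == 0:
                logger.warning("pair (%s -> %s): no distances; entry null", ref, tgt)
                mat.loc[ref, tgt] = np.nan
            else:
                mat.loc[ref, tgt] = s.median_distance
    mat.index.name = "reference"
    return mat
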