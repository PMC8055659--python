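"""Synthetic marked point patterns emulating multiplex-IF per-cell data.

The generator produces per-cell tables with the statistical structure the
downstream analysis assumes, so the whole pipeline is testable without the
(unavailable) clinical slides:

* malignant cells (CK+) from a Matérn cluster process — Poisson-distributed
  nest centres with uniform offspring in discs, reproducing the cohesive
  tumour-nest morphology;
* immune cells (T cells, macrophages) as Poisson counts placed either inside
  a random nest disc (with probability ``mixing``) or uniformly in the
  stromal complement — ``mixing`` is the tunable degree of immune
  infiltration into tumour nests;
* stromal/other nucleated cells as complete spatial randomness (CSR);
* marker positivity drawn per cell from class-conditional probabilities
  calibrated so phenotype densities rank like a typical NSCLC cohort
  (malignant ≫ T cells > cytotoxic T > macrophages > checkpoint-positive
  subsets);
* between-sample heterogeneity as independent log-normal abundance factors
  per cell class;
* a second timepoint (consecutive-section replicate, one week apart) as
  binomial thinning + positional jitter + a small fraction of new cells.

Cohorts default to the study design: 10 samples × 5 ROIs × 2 timepoints on
931 × 698 µm fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cell_tables import (
    DEFAULT_ROI_HEIGHT_UM,
    DEFAULT_ROI_WIDTH_UM,
    ROIFrame,
    validate_frame,
)
from .errors import ParameterError

CLASSES = ("malignant", "tcell", "macrophage", "other")

#: Markers simulated by default (the PD-L1/PD-1 T-cell panel layout).
DEFAULT_MARKERS = ["CK", "CD3", "CD8", "PD-1", "PD-L1", "CD68"]

#: Class-conditional positivity probabilities.  Unlisted markers are 0.
#: Calibrated so phenotype abundance ranks mirror a typical NSCLC cohort:
#: CK+ >> CD3+ > CD3+CD8+ > CK+PD-L1+ ≈ CD68+ > CD68+PD-L1+ > CD3+PD-1+
#: > CD3+CD8+PD-1+ (PD-1 and CD8 drawn independently given CD3+).
DEFAULT_MARKER_PROBS: dict[str, dict[str, float]] = {
    "malignant": {"CK": 1.0, "PD-L1": 0.04},
    "tcell": {"CD3": 1.0, "CD8": 0.72, "PD-1": 0.05},
    "macrophage": {"CD68": 1.0, "PD-L1": 0.69},
    "other": {},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Rates are expected counts per ROI; lengths are microns.
    """

    width: float = DEFAULT_ROI_WIDTH_UM
    height: float = DEFAULT_ROI_HEIGHT_UM
    n_samples: int = 10
    n_rois_per_sample: int = 5
    seed: int = 0
    nest_parent_rate: float = 8.0
    nest_radius: float = 120.0
    nest_offspring_mean: float = 250.0
    immune_rate: float = 400.0
    macrophage_rate: float = 75.0
    other_rate: float = 300.0
    mixing: float = 0.5
    markers: list[str] = field(default_factory=lambda: list(DEFAULT_MARKERS))
    marker_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(p) for c, p in DEFAULT_MARKER_PROBS.items()}
    )
    sample_sd: float = 0.5
    replicate_keep: float = 0.9
    replicate_add: float = 0.1
    jitter_sd: float = 2.0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ParameterError("ROI dimensions must be positive")
        if not (0.0 <= self.mixing <= 1.0):
            raise ParameterError(f"mixing must be in [0, 1], got {self.mixing}")
        if not (0.0 < self.replicate_keep <= 1.0):
            raise ParameterError(
                f"replicate_keep must be in (0, 1], got {self.replicate_keep}"
            )
        if self.replicate_add < 0:
            raise ParameterError("replicate_add must be >= 0")
        for name in (
            "nest_parent_rate",
            "nest_radius",
            "nest_offspring_mean",
            "immune_rate",
            "macrophage_rate",
            "other_rate",
            "sample_sd",
            "jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for cls, probs in self.marker_probs.items():
            if cls not in CLASSES:
                raise ParameterError(f"unknown cell class {cls!r}")
            for m, p in probs.items():
                if m not in self.markers:
                    raise ParameterError(f"marker_probs references undeclared marker {m!r}")
                if not (0.0 <= p <= 1.0):
                    raise ParameterError(f"probability {p} for {cls}/{m} outside [0, 1]")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_csr(
    rate: float, width: float, height: float, seed_or_rng=None
) -> np.ndarray:
    """Homogeneous Poisson (CSR) pattern with intensity ``rate`` points/µm².

    Count ~ Poisson(rate · width · height); positions i.i.d. uniform.
    """
    if rate < 0:
        raise ParameterError(f"rate must be >= 0, got {rate}")
    rng = _rng(seed_or_rng)
    n = rng.poisson(rate * width * height)
    pts = np.column_stack([rng.uniform(0, width, n), rng.uniform(0, height, n)])
    return pts


def _uniform_in_discs(
    rng: np.random.Generator,
    n: int,
    centers: np.ndarray,
    radius: float,
    width: float,
    height: float,
) -> np.ndarray:
    """n points, each uniform in a randomly chosen disc, clipped to the ROI by rejection."""
    out = np.empty((n, 2))
    todo = np.arange(n)
    disc = rng.integers(0, len(centers), n)
    for _ in range(10_000):
        if not len(todo):
            break
        k = len(todo)
        r = radius * np.sqrt(rng.random(k))
        th = rng.uniform(0, 2 * np.pi, k)
        pts = centers[disc[todo]] + np.column_stack([r * np.cos(th), r * np.sin(th)])
        ok = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= width)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= height)
        )
        out[todo[ok]] = pts[ok]
        todo = todo[~ok]
    else:
        raise RuntimeError("disc sampling failed to converge")
    return out


def _uniform_in_complement(
    rng: np.random.Generator,
    n: int,
    centers: np.ndarray,
    radius: float,
    width: float,
    height: float,
) -> np.ndarray:
    """n points uniform in the ROI outside every nest disc (rejection sampling)."""
    out = np.empty((n, 2))
    filled = 0
    for _ in range(10_000):
        if filled >= n:
            break
        k = max(n - filled, 32)
        pts = np.column_stack([rng.uniform(0, width, k), rng.uniform(0, height, k)])
        if len(centers):
            d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            ok = (d2 > radius * radius).all(axis=1)
            pts = pts[ok]
        take = min(len(pts), n - filled)
        out[filled : filled + take] = pts[:take]
        filled += take
    else:
        raise RuntimeError(
            "complement sampling failed: nest discs cover (almost) the whole ROI"
        )
    return out


def _draw_markers(
    rng: np.random.Generator,
    classes: np.ndarray,
    markers: list[str],
    marker_probs: Mapping[str, Mapping[str, float]],
) -> dict[str, np.ndarray]:
    n = len(classes)
    calls = {m: np.zeros(n, dtype=bool) for m in markers}
    for cls in CLASSES:
        idx = np.flatnonzero(classes == cls)
        if not len(idx):
            continue
        for m, p in marker_probs.get(cls, {}).items():
            calls[m][idx] = rng.random(len(idx)) < p
    return calls


def simulate_roi(
    config: SimConfig,
    sample_id: str = "S01",
    roi_id: str = "R1",
    seed_or_rng=None,
    sample_factors: Mapping[str, float] | None = None,
    timepoint: str = "week1",
) -> ROIFrame:
    """Generate one week-1 ROI frame under ``config``.

    ``sample_factors`` multiply the class rates (between-sample abundance
    heterogeneity); default 1.  The returned frame's ``meta`` records the
    ground-truth class of every cell, the nest centres, and the mixing
    fraction, for parameter-recovery tests.
    """
    config.validate()
    rng = _rng(seed_or_rng)
    f = {c: 1.0 for c in CLASSES}
    if sample_factors:
        f.update(sample_factors)
    W, H, R = config.width, config.height, config.nest_radius

    # malignant: Matérn cluster process, offspring kept inside the ROI
    n_parents = rng.poisson(config.nest_parent_rate * f["malignant"])
    nests = np.column_stack([rng.uniform(0, W, n_parents), rng.uniform(0, H, n_parents)])
    n_off = rng.poisson(config.nest_offspring_mean, n_parents)
    mal_pts = (
        np.vstack(
            [
                _uniform_in_discs(rng, k, c[None, :], R, W, H)
                for c, k in zip(nests, n_off)
                if k
            ]
        )
        if n_parents and n_off.sum()
        else np.empty((0, 2))
    )

    def _immune(rate_key: str, cls: str) -> np.ndarray:
        rate = getattr(config, rate_key) * f[cls]
        n = rng.poisson(rate)
        if n == 0:
            return np.empty((0, 2))
        if n_parents == 0:
            return np.column_stack([rng.uniform(0, W, n), rng.uniform(0, H, n)])
        inside = rng.random(n) < config.mixing
        pts = np.empty((n, 2))
        if inside.any():
            pts[inside] = _uniform_in_discs(rng, int(inside.sum()), nests, R, W, H)
        if (~inside).any():
            pts[~inside] = _uniform_in_complement(rng, int((~inside).sum()), nests, R, W, H)
        return pts

    t_pts = _immune("immune_rate", "tcell")
    m_pts = _immune("macrophage_rate", "macrophage")
    o_pts = simulate_csr(config.other_rate * f["other"] / (W * H), W, H, rng)

    pts = np.vstack([mal_pts, t_pts, m_pts, o_pts])
    classes = np.array(
        ["malignant"] * len(mal_pts)
        + ["tcell"] * len(t_pts)
        + ["macrophage"] * len(m_pts)
        + ["other"] * len(o_pts)
    )
    calls = _draw_markers(rng, classes, config.markers, config.marker_probs)

    cells = pd.DataFrame(
        {
            "cell_id": [f"{sample_id}_{roi_id}_w1_{i:05d}" for i in range(len(pts))],
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            **calls,
        }
    )
    frame = ROIFrame(
        sample_id,
        roi_id,
        timepoint,
        width=W,
        height=H,
        cells=cells,
        meta={
            "true_class": classes,
            "nests": nests,
            "mixing": config.mixing,
            "n_by_class": {c: int((classes == c).sum()) for c in CLASSES},
        },
    )
    validate_frame(frame, required_markers=config.markers)
    return frame


def replicate_timepoint(
    frame: ROIFrame,
    q: float = 0.9,
    eps: float = 0.1,
    jitter_sd: float = 2.0,
    seed_or_rng=None,
    timepoint: str = "week2",
    bootstrap_sd: float = 10.0,
) -> ROIFrame:
    """Consecutive-section replicate of ``frame`` (the second timepoint).

    Each cell is retained with probability ``q`` and its position jittered by
    an isotropic Gaussian of sd ``jitter_sd`` µm (clipped to the field);
    marker calls of retained cells are preserved.  Poisson(``eps``·n) new
    cells are added by class-preserving bootstrap: each copies the marker map
    of a uniformly chosen week-1 cell and is displaced by an isotropic
    Gaussian of sd ``bootstrap_sd`` µm, so new cells follow each class's
    spatial model (clustered classes stay clustered, CSR classes stay
    near-CSR).
    """
    if not (0.0 < q <= 1.0):
        raise ParameterError(f"q must be in (0, 1], got {q}")
    if eps < 0 or jitter_sd < 0:
        raise ParameterError("eps and jitter_sd must be >= 0")
    rng = _rng(seed_or_rng)
    n = frame.n_cells
    keep = rng.random(n) < q
    kept = frame.cells.loc[keep].reset_index(drop=True)
    jitter = rng.normal(0.0, jitter_sd, (len(kept), 2)) if jitter_sd > 0 else 0.0
    xy = kept[["x_um", "y_um"]].to_numpy() + jitter
    kept["x_um"] = np.clip(xy[:, 0], 0, frame.width)
    kept["y_um"] = np.clip(xy[:, 1], 0, frame.height)

    n_new = rng.poisson(eps * n) if n else 0
    if n_new:
        src = rng.integers(0, n, n_new)
        new = frame.cells.iloc[src].reset_index(drop=True)
        disp = rng.normal(0.0, bootstrap_sd, (n_new, 2))
        new["x_um"] = np.clip(new["x_um"].to_numpy() + disp[:, 0], 0, frame.width)
        new["y_um"] = np.clip(new["y_um"].to_numpy() + disp[:, 1], 0, frame.height)
        cells = pd.concat([kept, new], ignore_index=True)
    else:
        src = np.empty(0, dtype=int)
        cells = kept

    prefix = f"{frame.sample_id}_{frame.roi_id}_w2_"
    cells["cell_id"] = [f"{prefix}{i:05d}" for i in range(len(cells))]

    meta = dict(frame.meta)
    if "true_class" in meta:
        tc = np.asarray(meta["true_class"])
        new_tc = np.concatenate([tc[keep], tc[src]]) if len(tc) == n else None
        if new_tc is not None:
            meta = {**meta, "true_class": new_tc,
                    "n_by_class": {c: int((new_tc == c).sum()) for c in CLASSES}}

    out = ROIFrame(
        frame.sample_id,
        frame.roi_id,
        timepoint,
        width=frame.width,
        height=frame.height,
        cells=cells,
        meta=meta,
    )
    validate_frame(out)
    return out


def sample_factors(config: SimConfig, rng: np.random.Generator) -> dict[str, float]:
    """Independent log-normal abundance factors per cell class (sd on the log scale)."""
    return {c: float(np.exp(rng.normal(0.0, config.sample_sd))) for c in CLASSES}


def simulate_cohort(config: SimConfig | None = None) -> tuple[list[ROIFrame], dict]:
    """Generate the full two-timepoint cohort under ``config`` (default study design).

    Returns ``(frames, truth)``: frames for every (sample, ROI) at week1 and
    week2, and a ground-truth dict with the per-sample abundance factors,
    per-ROI class counts, and the mixing fraction — the inputs to
    parameter-recovery tests.

    Seeding: a master ``SeedSequence(config.seed)`` is spawned once per
    sample; each sample stream is spawned per ROI into a week-1 and a week-2
    substream, so any ROI is re-generable in isolation from the master seed.
    """
    config = config or SimConfig()
    config.validate()
    master = np.random.SeedSequence(config.seed)
    frames: list[ROIFrame] = []
    truth: dict = {"mixing": config.mixing, "seed": config.seed, "samples": {}}
    for s_seq in master.spawn(config.n_samples):
        i = len(truth["samples"]) + 1
        sid = f"S{i:02d}"
        child = s_seq.spawn(config.n_rois_per_sample + 1)
        factors = sample_factors(config, np.random.default_rng(child[0]))
        s_truth = {"factors": factors, "rois": {}}
        for j, roi_seq in enumerate(child[1:], start=1):
            rid = f"R{j}"
            w1_seq, w2_seq = roi_seq.spawn(2)
            f1 = simulate_roi(
                config, sid, rid, np.random.default_rng(w1_seq), sample_factors=factors
            )
            f2 = replicate_timepoint(
                f1,
                q=config.replicate_keep,
                eps=config.replicate_add,
                jitter_sd=config.jitter_sd,
                seed_or_rng=np.random.default_rng(w2_seq),
            )
            frames.extend([f1, f2])
            s_truth["rois"][rid] = {
                "n_by_class_week1": f1.meta["n_by_class"],
                "n_by_class_week2": f2.meta["n_by_class"],
            }
        truth["samples"][sid] = s_truth
    return frames, truth


def with_mixing(config: SimConfig, m: float) -> SimConfig:
    """Copy of ``config`` with the immune-infiltration fraction set to ``m``."""
    return replace(config, mixing=m)
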