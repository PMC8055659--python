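"""Two-timepoint reproducibility statistics.

The assay's analytical reproducibility is assessed by staining consecutive
sections of every sample one week apart and re-quantifying phenotype
percentages at the same ROI locations.  Agreement is summarised three ways:

* per-ROI coefficient of variation (CV) of the two percentages — with two
  observations and sample sd (ddof=1), CV(a, b) = |a − b| / (√2 · mean);
  one CV per ROI per sample gives n_ROIs × n_samples CVs per phenotype;
* within-sample Spearman rank correlation — week-1 vs week-2 percent
  vectors over one sample's ROIs, one ρ per sample;
* across-sample Spearman — sample-level mean percents, week 1 vs week 2,
  one ρ per phenotype, with Bonferroni adjustment within each panel family.

Benchmarks from practice: median CV below 0.5, median within-sample ρ above
0.5, across-sample ρ above 0.7 indicate a reproducible phenotype.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .phenotyping import TOTAL_PHENOTYPE

logger = logging.getLogger(__name__)

#: Benchmark thresholds: median CV, median within-sample rho, across-sample rho.
CV_BENCHMARK = 0.5
RHO_WITHIN_BENCHMARK = 0.5
RHO_ACROSS_BENCHMARK = 0.7


def cv_two_timepoints(a, b):
    """Coefficient of variation of a paired two-timepoint observation.

    Sample standard deviation (ddof=1) over the pair divided by the pair
    mean: CV = |a − b| / (√2 · mean).  Both-zero pairs return 0 by
    convention (perfectly reproducible absence).  Accepts scalars or arrays.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ParameterError("CV inputs must be non-negative")
    mean = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.abs(a - b) / (math.sqrt(2.0) * mean)
    cv = np.where(mean == 0, 0.0, cv)
    return float(cv) if cv.ndim == 0 else cv


def spearman_within_sample(week1, week2) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p.

    Returns ``(nan, nan)`` with a warning when fewer than 3 pairs or when
    either vector is constant (rank correlation undefined).
    """
    w1 = np.asarray(week1, dtype=float)
    w2 = np.asarray(week2, dtype=float)
    if w1.shape != w2.shape:
        raise ParameterError("paired vectors must have equal length")
    if len(w1) < 3:
        logger.warning("Spearman undefined for fewer than 3 paired ROIs")
        return (float("nan"), float("nan"))
    if np.ptp(w1) == 0 or np.ptp(w2) == 0:
        logger.warning("Spearman undefined for a constant vector")
        return (float("nan"), float("nan"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(w1, w2)
    return (float(rho), float(p))


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m·p) with m the family size."""
    p = np.asarray(p_values, dtype=float)
    finite = p[~np.isnan(p)]
    if ((finite < 0) | (finite > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


@dataclass
class ReproStat:
    """Reproducibility summary for one phenotype of one panel."""

    phenotype: str
    panel: str
    cv_per_roi: list[float]
    median_cv: float
    rho_within: dict[str, float]
    median_rho_within: float
    rho_across: float
    p_raw: float
    p_adj: float = float("nan")
    flags: dict[str, bool] = field(default_factory=dict)


def summarize_repro(
    density_table: pd.DataFrame,
    *,
    min_present_fraction: float = 0.5,
    across_mode: str = "sample_means",
) -> tuple[list[ReproStat], list[str]]:
    """Full reproducibility battery over a two-timepoint density table.

    Parameters
    ----------
    density_table
        Output of :func:`mifspat.phenotyping.density_table` containing both
        timepoints (exactly two timepoint labels).
    min_present_fraction
        Phenotypes with zero counts in at least ``1 − min_present_fraction``
        of ROIs are excluded from the battery (scarce phenotypes make the
        rank statistics meaningless) and returned in the exclusion list.
    across_mode
        ``"sample_means"`` (default): across-sample ρ over sample-level mean
        percents.  ``"pooled_rois"``: over all (sample, ROI) points pooled.

    Returns
    -------
    (stats, excluded): one :class:`ReproStat` per retained phenotype per
    panel, with Bonferroni adjustment per panel family; the names of
    excluded phenotypes as ``"panel:phenotype"`` strings.
    """
    if across_mode not in ("sample_means", "pooled_rois"):
        raise ParameterError(f"unknown across_mode {across_mode!r}")
    df = density_table[density_table["phenotype"] != TOTAL_PHENOTYPE]
    timepoints = sorted(df["timepoint"].unique())
    if len(timepoints) != 2:
        raise ValidationError(
            f"need exactly two timepoints, found {timepoints}"
        )
    t1, t2 = timepoints

    stats_out: list[ReproStat] = []
    excluded: list[str] = []
    for panel, pdf in df.groupby("panel", sort=True):
        panel_stats: list[ReproStat] = []
        for phen, g in pdf.groupby("phenotype", sort=True):
            wide_pct = g.pivot_table(
                index=["sample_id", "roi_id"], columns="timepoint",
                values="percent_dapi", aggfunc="first",
            )
            wide_cnt = g.pivot_table(
                index=["sample_id", "roi_id"], columns="timepoint",
                values="count", aggfunc="first",
            )
            if wide_pct[[t1, t2]].isna().any().any():
                orphans = wide_pct.index[wide_pct[[t1, t2]].isna().any(axis=1)]
                raise ValidationError(
                    f"panel {panel}, {phen}: unmatched (sample, roi) keys "
                    f"across timepoints: {list(orphans)}"
                )
            present = (wide_cnt[[t1, t2]] > 0).any(axis=1).mean()
            if present < min_present_fraction:
                excluded.append(f"{panel}:{phen}")
                logger.warning(
                    "panel %s phenotype %s excluded from reproducibility "
                    "battery (present in %.0f%% of ROIs)", panel, phen,
                    100 * present,
                )
                continue

            a = wide_pct[t1].to_numpy(dtype=float)
            b = wide_pct[t2].to_numpy(dtype=float)
            cvs = cv_two_timepoints(a, b)
            rho_within = {}
            for sid, sg in wide_pct.groupby(level="sample_id"):
                rho, _ = spearman_within_sample(sg[t1], sg[t2])
                rho_within[str(sid)] = rho

            if across_mode == "sample_means":
                means = wide_pct.groupby(level="sample_id").mean()
                rho_across, p_raw = spearman_within_sample(means[t1], means[t2])
            else:
                rho_across, p_raw = spearman_within_sample(a, b)

            within_vals = np.array(list(rho_within.values()), dtype=float)
            panel_stats.append(
                ReproStat(
                    phenotype=str(phen),
                    panel=str(panel),
                    cv_per_roi=[float(v) for v in np.atleast_1d(cvs)],
                    median_cv=float(np.median(cvs)),
                    rho_within=rho_within,
                    median_rho_within=float(np.nanmedian(within_vals))
                    if np.isfinite(within_vals).any()
                    else float("nan"),
                    rho_across=rho_across,
                    p_raw=p_raw,
                )
            )
        # Bonferroni family: phenotypes within one panel
        p_adj = bonferroni([s.p_raw for s in panel_stats])
        for s, pa in zip(panel_stats, p_adj):
            s.p_adj = float(pa)
            s.flags = {
                "median_cv_ok": s.median_cv <= CV_BENCHMARK,
                "rho_within_ok": s.median_rho_within >= RHO_WITHIN_BENCHMARK,
                "rho_across_ok": s.rho_across >= RHO_ACROSS_BENCHMARK,
            }
        logger.info("panel %s: Bonferroni family size %d", panel, len(panel_stats))
        stats_out.extend(panel_stats)
    return stats_out, excluded


def repro_frame(stats_list: list[ReproStat]) -> pd.DataFrame:
    """Flatten ReproStat records into a tidy per-phenotype DataFrame."""
    rows = []
    for s in stats_list:
        rows.append(
            {
                "panel": s.panel,
                "phenotype": s.phenotype,
                "n_cv": len(s.cv_per_roi),
                "median_cv": s.median_cv,
                "median_rho_within": s.median_rho_within,
                "rho_across": s.rho_across,
                "p_raw": s.p_raw,
                "p_adj": s.p_adj,
                **{k: v for k, v in s.flags.items()},
            }
        )
    return pd.DataFrame(rows)
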