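"""Co-expression phenotyping and density / percentage quantification.

A phenotype is a named marker co-expression rule: a set of markers required
positive and (optionally) a set required negative, e.g. ``CD3+CD8+`` for
cytotoxic T cells or ``CD3+FOXP3+CD8-`` for regulatory T cells.  Membership
is NON-exclusive: a CD3+CD8+ cell is also a member of CD3+, matching the
overlapping phenotype rows reported for immuno-oncology panels.  Markers a
rule does not mention are don't-care.

Densities are counts normalised per mm² of ROI area; percentages divide each
phenotype's count by the total nucleated (DAPI+) cell count of the same ROI
— all segmented cells carry a DAPI-stained nucleus, so the denominator is
every cell in the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .cell_tables import ROIFrame
from .errors import ParameterError, ValidationError

#: Phenotype name used for the total-nucleated-cell denominator row.
TOTAL_PHENOTYPE = "DAPI+"

#: Marker vocabulary across the five shipped panels, used to tokenise
#: field notation such as ``CD3+FOXP3+CD8-`` (hyphens are part of marker
#: names, not separators).
KNOWN_MARKERS = [
    "CK",
    "CD3",
    "CD8",
    "PD-1",
    "PD-L1",
    "CD68",
    "CD45RO",
    "GBZ",
    "FOXP3",
    "B7-H3",
    "B7-H4",
    "IDO-1",
    "ICOS",
    "LAG3",
    "OX-40",
    "OX40",
    "TIM3",
    "VISTA",
    "Arg-1",
    "CD11b",
    "CD14",
    "CD33",
    "CD66b",
]

DENSITY_COLUMNS = [
    "sample_id",
    "roi_id",
    "timepoint",
    "panel",
    "phenotype",
    "count",
    "density_cells_mm2",
    "percent_dapi",
]


@dataclass(frozen=True)
class PhenotypeRule:
    """A co-expression rule: all ``positive`` markers true and all ``negative`` false."""

    name: str
    positive: frozenset[str]
    negative: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.positive:
            raise ParameterError(f"rule {self.name!r}: empty positive marker set")
        if self.positive & self.negative:
            raise ParameterError(
                f"rule {self.name!r}: markers {sorted(self.positive & self.negative)} "
                "required both positive and negative"
            )

    @classmethod
    def from_name(cls, name: str, markers: Iterable[str] | None = None) -> "PhenotypeRule":
        """Parse a rule from field notation, e.g. ``CD3+FOXP3+CD8-``.

        Marker names themselves contain hyphens (PD-1, B7-H3), so the string
        is tokenised against a marker vocabulary (``markers`` plus the
        built-in :data:`KNOWN_MARKERS`), longest match first, each token
        followed by ``+`` (required positive) or ``-`` (required negative).
        """
        vocab = sorted(set(KNOWN_MARKERS) | set(markers or ()), key=len, reverse=True)
        pos, neg = set(), set()
        i = 0
        while i < len(name):
            for m in vocab:
                if name.startswith(m, i) and len(name) > i + len(m) and name[
                    i + len(m)
                ] in "+-":
                    sign = name[i + len(m)]
                    (pos if sign == "+" else neg).add(m)
                    i += len(m) + 1
                    break
            else:
                raise ParameterError(
                    f"cannot parse phenotype notation {name!r} at position {i}"
                )
        return cls(name=name, positive=frozenset(pos), negative=frozenset(neg))


@dataclass
class PanelSpec:
    """One staining panel: its ordered marker list and phenotype rules."""

    panel_id: str
    markers: list[str]
    rules: list[PhenotypeRule] = field(default_factory=list)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValidationError(f"panel {self.panel_id}: duplicate rule names")
        declared = set(self.markers)
        for r in self.rules:
            undeclared = (r.positive | r.negative) - declared
            if undeclared:
                raise ValidationError(
                    f"panel {self.panel_id}: rule {r.name!r} references "
                    f"undeclared marker(s) {sorted(undeclared)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "PanelSpec":
        markers = list(d["markers"])
        rules = []
        descriptions = {}
        for item in d.get("phenotypes", []):
            if isinstance(item, str):
                rules.append(PhenotypeRule.from_name(item, markers))
            else:
                name = item["name"]
                rules.append(PhenotypeRule.from_name(name, markers))
                if "description" in item:
                    descriptions[name] = item["description"]
        return cls(
            panel_id=str(d["panel_id"]),
            markers=list(d["markers"]),
            rules=rules,
            descriptions=descriptions,
        )


def load_panel(path: str | Path) -> PanelSpec:
    """Load a panel definition from a YAML file."""
    with open(path) as fh:
        return PanelSpec.from_dict(yaml.safe_load(fh))


def default_panels() -> dict[str, PanelSpec]:
    """The five shipped immuno-oncology panel definitions, keyed by panel id."""
    panels = {}
    pkg = resources.files("mifspat") / "panels"
    for entry in sorted(p.name for p in pkg.iterdir() if p.name.endswith(".yaml")):
        with (pkg / entry).open() as fh:
            spec = PanelSpec.from_dict(yaml.safe_load(fh))
        panels[spec.panel_id] = spec
    return panels


def assign_phenotypes(frame: ROIFrame, panel: PanelSpec) -> dict[str, set[str]]:
    """Map each rule name to the set of member cell ids (non-exclusive)."""
    masks = phenotype_masks(frame, panel)
    ids = frame.cells["cell_id"]
    return {name: set(ids[mask]) for name, mask in masks.items()}


def phenotype_masks(frame: ROIFrame, panel: PanelSpec) -> dict[str, np.ndarray]:
    """Boolean membership mask per rule, aligned to ``frame.cells`` rows."""
    df = frame.cells
    missing = [m for m in panel.markers if m not in df.columns]
    if missing:
        raise ValidationError(
            f"frame {frame.key()}: panel {panel.panel_id} marker(s) {missing} absent"
        )
    out: dict[str, np.ndarray] = {}
    for rule in panel.rules:
        mask = np.ones(len(df), dtype=bool)
        for m in rule.positive:
            mask &= df[m].to_numpy(dtype=bool)
        for m in rule.negative:
            mask &= ~df[m].to_numpy(dtype=bool)
        out[rule.name] = mask
    return out


def compute_densities(frame: ROIFrame, panel: PanelSpec) -> pd.DataFrame:
    """Per-rule counts and densities (cells/mm²) for one ROI frame.

    Returns one row per rule plus a ``DAPI+`` row counting every cell;
    the ``percent_dapi`` column is left unfilled (see
    :func:`percent_of_total`).
    """
    if frame.area_mm2 <= 0:
        raise ParameterError(f"frame {frame.key()}: zero or negative ROI area")
    masks = phenotype_masks(frame, panel)
    rows = []
    for name in [TOTAL_PHENOTYPE, *(r.name for r in panel.rules)]:
        count = frame.n_cells if name == TOTAL_PHENOTYPE else int(masks[name].sum())
        rows.append(
            {
                "sample_id": frame.sample_id,
                "roi_id": frame.roi_id,
                "timepoint": frame.timepoint,
                "panel": panel.panel_id,
                "phenotype": name,
                "count": count,
                "density_cells_mm2": count / frame.area_mm2,
                "percent_dapi": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=DENSITY_COLUMNS)


def percent_of_total(records: pd.DataFrame) -> pd.DataFrame:
    """Fill ``percent_dapi`` = 100 · count / DAPI+ count within each ROI group.

    Equivalent to the ratio of densities — the ROI area cancels.  Groups
    whose DAPI+ total is zero are flagged with a warning and keep NaN
    percents.
    """
    out = records.copy()
    group_cols = ["sample_id", "roi_id", "timepoint", "panel"]

    def _fill(grp: pd.DataFrame) -> pd.DataFrame:
        total_rows = grp.loc[grp["phenotype"] == TOTAL_PHENOTYPE, "count"]
        if total_rows.empty:
            raise ValidationError(
                f"group {tuple(grp.iloc[0][group_cols])}: no {TOTAL_PHENOTYPE} row"
            )
        total = int(total_rows.iloc[0])
        if total == 0:
            import logging

            logging.getLogger(__name__).warning(
                "group %s: zero total cells, percents undefined",
                tuple(grp.iloc[0][group_cols]),
            )
            return grp
        grp = grp.copy()
        grp["percent_dapi"] = 100.0 * grp["count"] / total
        return grp

    out = (
        out.groupby(group_cols, group_keys=False, sort=False)[out.columns]
        .apply(_fill)
        .reset_index(drop=True)
    )
    return out


def density_table(
    frames: Iterable[ROIFrame], panels: Sequence[PanelSpec] | PanelSpec
) -> pd.DataFrame:
    """Density + percent table over many frames (and optionally many panels)."""
    if isinstance(panels, PanelSpec):
        panels = [panels]
    parts = [compute_densities(f, p) for f in frames for p in panels]
    if not parts:
        return pd.DataFrame(columns=DENSITY_COLUMNS)
    return percent_of_total(pd.concat(parts, ignore_index=True))
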