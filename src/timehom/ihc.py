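"""IHC quantification: positive index, ordinal score, and cell density.

Each tumor section is examined in a number of high-power fields (HPF,
x400, default area 0.0788 mm^2).  In every field the number of
marker-positive cells among a fixed number of assessed cells (default 100)
is recorded.  Three per-section summaries are derived:

* positive index  — mean percentage of positive cells over the fields;
* ordinal score   — 0..3 binning of the positive index
                    (<1% -> 0, 1-10% -> 1, 10-50% -> 2, >50% -> 3);
* cell density    — mean positive cells per field divided by the field
                    area, in positive cells / mm^2.

TLS (tertiary lymphoid structures) are taken as an externally supplied
count per section; no image analysis is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import MarkerPanel, DEFAULT_PANEL

DEFAULT_FIELD_AREA_MM2 = 0.0788
DEFAULT_CELLS_ASSESSED = 100
#: Positive-index bin edges for scores 1|2|3; the first bin [0, 1) is score 0.
DEFAULT_SCORE_EDGES = (1.0, 10.0, 50.0)


@dataclass(frozen=True)
class FieldObservation:
    """One high-power field: positives among ``cells_assessed`` cells."""

    positive_count: int
    cells_assessed: int = DEFAULT_CELLS_ASSESSED
    field_area: float = DEFAULT_FIELD_AREA_MM2

    def __post_init__(self) -> None:
        if self.cells_assessed <= 0:
            raise ValueError("cells_assessed must be positive")
        if self.field_area <= 0:
            raise ValueError("field_area must be positive")
        if not 0 <= self.positive_count <= self.cells_assessed:
            raise ValueError(
                f"positive_count={self.positive_count} outside "
                f"[0, cells_assessed={self.cells_assessed}]"
            )


@dataclass
class RegionalSample:
    """Quantified immune profile of one tumor region (section)."""

    tumor_id: str
    region: str
    positive_index: dict[str, float]
    score: dict[str, int]
    density: dict[str, float]
    tls_count: int = 0


def positive_index(fields: Sequence[FieldObservation]) -> float:
    """Mean percentage of positive cells across high-power fields.

    Averages ``100 * positive_count / cells_assessed`` over the fields.
    """
    if len(fields) == 0:
        raise ValueError("positive_index requires at least one field")
    fracs = [100.0 * f.positive_count / f.cells_assessed for f in fields]
    return float(np.mean(fracs))


def score_positive_index(
    pct: float | np.ndarray,
    edges: tuple[float, float, float] = DEFAULT_SCORE_EDGES,
) -> int | np.ndarray:
    """Bin a positive index (percentage) into the ordinal 0-3 score.

    Boundary convention: [0, e0) -> 0, [e0, e1] -> 1, (e1, e2] -> 2,
    (e2, 100] -> 3.  With the default edges (1, 10, 50) this places 10%
    in score 1 and 50% in score 2 (">50%" is required for score 3).
    """
    arr = np.asarray(pct, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise ValueError("positive index must lie in [0, 100]")
    e0, e1, e2 = edges
    score = np.where(arr < e0, 0, 1 + (arr > e1).astype(int) + (arr > e2).astype(int))
    if np.isscalar(pct) or np.ndim(pct) == 0:
        return int(score)
    return score.astype(int)


def cell_density(fields: Sequence[FieldObservation]) -> float:
    """Positive cells per mm^2: mean count per field / field area."""
    if len(fields) == 0:
        raise ValueError("cell_density requires at least one field")
    areas = {f.field_area for f in fields}
    if len(areas) != 1:
        raise ValueError(f"inconsistent field_area across fields: {sorted(areas)}")
    area = areas.pop()
    return float(np.mean([f.positive_count for f in fields]) / area)


def quantify_section(
    tumor_id: str,
    region: str,
    marker_fields: Mapping[str, Sequence[FieldObservation]],
    tls_count: int = 0,
    panel: MarkerPanel = DEFAULT_PANEL,
) -> RegionalSample:
    """Aggregate the per-marker field observations of one section."""
    missing = [m for m in panel.markers if m not in marker_fields]
    if missing:
        raise ValueError(f"missing marker(s) in section {tumor_id}/{region}: {missing}")
    if tls_count < 0:
        raise ValueError("tls_count must be non-negative")
    idx: dict[str, float] = {}
    sco: dict[str, int] = {}
    den: dict[str, float] = {}
    for m in panel.markers:
        fields = marker_fields[m]
        idx[m] = positive_index(fields)
        sco[m] = int(score_positive_index(idx[m]))
        den[m] = cell_density(fields)
    return RegionalSample(tumor_id, region, idx, sco, den, int(tls_count))


def quantify_cohort(
    fields_df: pd.DataFrame,
    tls_df: pd.DataFrame | None = None,
    panel: MarkerPanel = DEFAULT_PANEL,
    field_area: float = DEFAULT_FIELD_AREA_MM2,
) -> pd.DataFrame:
    """Quantify every tumor x region section of a field-level sample sheet.

    Parameters
    ----------
    fields_df
        Columns ``tumor_id, region, marker, field_index, positive_count,
        cells_assessed`` (one row per field).
    tls_df
        Optional columns ``tumor_id, region, tls_count``.

    Returns
    -------
    One row per tumor x region with per-marker columns
    ``<marker>_index``, ``<marker>_score``, ``<marker>_density`` and a
    ``tls_count`` column.
    """
    required = {"tumor_id", "region", "marker", "positive_count", "cells_assessed"}
    missing_cols = required - set(fields_df.columns)
    if missing_cols:
        raise ValueError(f"IHC field sheet missing columns: {sorted(missing_cols)}")
    rows = []
    for (tid, region), grp in fields_df.groupby(["tumor_id", "region"], sort=True):
        rec: dict[str, object] = {"tumor_id": tid, "region": region}
        present = set(grp["marker"])
        missing = [m for m in panel.markers if m not in present]
        if missing:
            raise ValueError(f"missing marker(s) in section {tid}/{region}: {missing}")
        for m in panel.markers:
            g = grp[grp["marker"] == m]
            pct = float((100.0 * g["positive_count"] / g["cells_assessed"]).mean())
            rec[f"{m}_index"] = pct
            rec[f"{m}_score"] = int(score_positive_index(pct))
            rec[f"{m}_density"] = float(g["positive_count"].mean() / field_area)
        rows.append(rec)
    out = pd.DataFrame(rows)
    if tls_df is not None:
        out = out.merge(
            tls_df[["tumor_id", "region", "tls_count"]],
            on=["tumor_id", "region"],
            how="left",
        )
        if out["tls_count"].isna().any():
            bad = out.loc[out["tls_count"].isna(), ["tumor_id", "region"]]
            raise ValueError(f"TLS count missing for sections: {bad.to_records(index=False)}")
        out["tls_count"] = out["tls_count"].astype(int)
    else:
        out["tls_count"] = 0
    return out


def score_table(samples: pd.DataFrame, marker: str) -> pd.DataFrame:
    """Per-tumor tally of sections at each ordinal score for one marker.

    Returns one row per tumor with ``n_sections`` and, for each score s in
    0..3, ``score<s>_n`` and ``score<s>_pct`` (percentages of the tumor's
    sections; they sum to 100 per tumor).
    """
    col = f"{marker}_score"
    if col not in samples.columns:
        raise ValueError(f"no score column for marker {marker!r}")
    rows = []
    for tid, grp in samples.groupby("tumor_id", sort=True):
        n = len(grp)
        rec: dict[str, object] = {"tumor_id": tid, "n_sections": n}
        counts = grp[col].value_counts()
        for s in range(4):
            c = int(counts.get(s, 0))
            rec[f"score{s}_n"] = c
            rec[f"score{s}_pct"] = 100.0 * c / n
        rows.append(rec)
    return pd.DataFrame(rows)
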