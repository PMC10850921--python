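"""Seed morphometrics: dimension summaries, CT-derived volumes and
interspecific volume ratios.

Volumes come from labelled voxel grids (background / pericarp /
endosperm); total capsule volume is pericarp plus endosperm. The
interspecific ratio is the ratio of group means (per-seed pairings do
not exist), the aggregate reported for domesticated-versus-wild
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABEL_BACKGROUND, LABEL_PERICARP, LABEL_ENDOSPERM = 0, 1, 2


@dataclass(frozen=True)
class VolumeRecord:
    sample_id: str
    taxon: str
    total_volume: float
    endosperm_volume: float

    def __post_init__(self) -> None:
        if not 0 < self.endosperm_volume <= self.total_volume:
            raise ValueError(
                "need 0 < endosperm_volume <= total_volume "
                f"(got {self.endosperm_volume} / {self.total_volume})")


def summarize_dims(records: pd.DataFrame, group_by: str = "taxon"
                   ) -> pd.DataFrame:
    """Per-group mean and sample SD (ddof=1) of seed height and width.

    Groups with a single record report SD 0 with sd_defined=False.
    """
    value_cols = [c for c in ("height_mm", "width_mm") if c in records.columns]
    if not value_cols:
        raise ValueError("no height_mm/width_mm columns to summarize")
    if group_by not in records.columns:
        raise ValueError(f"missing grouping column {group_by!r}")
    rows = []
    for key, grp in records.groupby(group_by, sort=True):
        if len(grp) == 0:
            continue
        row = {"group": key, "n": len(grp), "sd_defined": len(grp) > 1}
        for c in value_cols:
            row[f"{c}_mean"] = float(grp[c].mean())
            row[f"{c}_sd"] = float(grp[c].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def volumes_from_mask(mask: np.ndarray, voxel_edge: float,
                      sample_id: str = "sample", taxon: str = "unknown"
                      ) -> VolumeRecord:
    """Capsule volumes from a labelled voxel grid.

    endosperm volume = endosperm voxels x voxel_edge^3; total volume =
    (pericarp + endosperm) voxels x voxel_edge^3.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be positive")
    labels = np.unique(mask)
    if set(labels.tolist()) - {LABEL_BACKGROUND, LABEL_PERICARP,
                               LABEL_ENDOSPERM}:
        raise ValueError("mask labels must be 0 (background), 1 (pericarp), "
                         "2 (endosperm)")
    n_endo = int((mask == LABEL_ENDOSPERM).sum())
    n_peri = int((mask == LABEL_PERICARP).sum())
    if n_endo == 0:
        raise ValueError("empty endosperm label")
    v = voxel_edge ** 3
    return VolumeRecord(sample_id, taxon,
                        total_volume=(n_endo + n_peri) * v,
                        endosperm_volume=n_endo * v)


def endosperm_fraction(v: VolumeRecord) -> float:
    """Endosperm share of total capsule volume, in (0, 1]."""
    return v.endosperm_volume / v.total_volume


def interspecific_ratio(a: pd.DataFrame, b: pd.DataFrame,
                        quantity: str = "total") -> dict:
    """Ratio of group means mean(a)/mean(b) for total or endosperm
    volume, with group sizes."""
    col = {"total": "total_volume_mm3",
           "endosperm": "endosperm_volume_mm3"}.get(quantity)
    if col is None:
        raise ValueError("quantity must be 'total' or 'endosperm'")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    return {"ratio": float(a[col].mean() / b[col].mean()),
            "n_a": len(a), "n_b": len(b), "quantity": quantity}
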