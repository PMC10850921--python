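"""Flow-cytometry genome-size estimation and ploidy inference.

DNA content is read off the ratio of the sample's fluorescence peak to a
co-processed internal standard of known 1C size (rice, 373,245,519 bp):
size_1C = (sample_peak / internal_peak) x internal_size. Fluorescence is
assumed linear in DNA content with a single internal standard, which is
exactly how the published peak table is computed. Ploidy is called
relative to a diploid baseline 1C size: ploidy = 2 x round(size /
baseline), rounded half up, so a sample at about twice the diploid
baseline is tetraploid.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datasets import RICE_1C_BP


@dataclass(frozen=True)
class FlowPeak:
    """One sample's peak pair with its internal standard."""

    sample_id: str
    sample_peak: float
    internal_peak: float
    internal_size: float = RICE_1C_BP

    def __post_init__(self) -> None:
        if self.sample_peak <= 0 or self.internal_peak <= 0:
            raise ValueError("peak positions must be positive")
        if self.internal_size <= 0:
            raise ValueError("internal standard size must be positive")


@dataclass(frozen=True)
class PloidyCall:
    size_1c: float
    ploidy: int
    baseline_1c: float
    ratio: float


def estimate_genome_size(p: FlowPeak) -> float:
    """1C genome size in bp from a peak pair; scale-invariant in the
    (arbitrary) fluorescence units."""
    return p.sample_peak / p.internal_peak * p.internal_size


def infer_ploidy(size_1c: float, baseline_diploid_1c: float) -> PloidyCall:
    """Even ploidy level relative to a known-diploid baseline 1C size."""
    if size_1c <= 0 or baseline_diploid_1c <= 0:
        raise ValueError("sizes must be positive")
    ratio = size_1c / baseline_diploid_1c
    if ratio < 0.25:
        raise ValueError(
            f"size/baseline ratio {ratio:.3f} < 0.25: implausible internal "
            "standard or baseline")
    import math

    ploidy = 2 * max(1, math.floor(ratio + 0.5))  # round half up
    return PloidyCall(size_1c, ploidy, baseline_diploid_1c, ratio)


def batch_report(peaks: pd.DataFrame, baseline: float | str = "diploid-median"
                 ) -> pd.DataFrame:
    """Per-sample genome sizes and ploidy for a peak table.

    `peaks` needs columns sample_id, peak, internal_peak, internal_size
    (plus diploid_flag when baseline='diploid-median'). `baseline` is a
    fixed diploid 1C size in bp, or 'diploid-median' to use the median
    estimated size of rows flagged diploid.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak table")
    df = peaks.copy()
    df["genome_size_bp"] = [
        estimate_genome_size(FlowPeak(str(r.sample_id), float(r.peak),
                                      float(r.internal_peak),
                                      float(r.internal_size)))
        for r in df.itertuples()
    ]
    if baseline == "diploid-median":
        if "diploid_flag" not in df.columns or not df["diploid_flag"].any():
            raise ValueError(
                "baseline='diploid-median' needs rows with diploid_flag set")
        base = float(df.loc[df["diploid_flag"] == 1, "genome_size_bp"].median())
    else:
        base = float(baseline)
    calls = [infer_ploidy(s, base) for s in df["genome_size_bp"]]
    df["baseline_1c_bp"] = base
    df["size_ratio"] = [c.ratio for c in calls]
    df["ploidy"] = [c.ploidy for c in calls]
    return df


def report_text(report: pd.DataFrame) -> str:
    cols = [c for c in ("sample_id", "species", "site", "peak",
                        "internal_peak", "genome_size_bp", "ploidy")
            if c in report.columns]
    out = report[cols].copy()
    out["genome_size_bp"] = out["genome_size_bp"].map(lambda x: f"{x:,.0f}")
    return out.to_string(index=False) + "\n"
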