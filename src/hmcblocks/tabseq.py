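"""Single-base 5mC/5hmC arithmetic from paired bisulfite conversions.

In TAB-Seq the C/(C+T) ratio of the oxidized sample reads out 5hmC
directly, while the untreated bisulfite ratio reads out 5mC + 5hmC at the
same CpG.  Subtracting the two gives 5mC; negative differences (sampling
noise) are clipped to zero.  No correction is applied for bisulfite
non-conversion or incomplete oxidation — both efficiencies default to
perfect and can be supplied if measured.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "site_levels",
    "add_levels",
    "interval_mean",
    "concordance",
    "read_tabseq",
]

TABSEQ_COLUMNS = ["chrom", "pos", "ox_c", "ox_t", "bs_c", "bs_t"]


def site_levels(
    ox_ratio, bs_ratio, conversion: float = 1.0, oxidation: float = 1.0
):
    """Per-CpG (5hmC, 5mC) levels from oxidized and untreated C/(C+T) ratios.

    hmc = ox_ratio / oxidation; mc = max(0, bs_ratio - hmc), with the
    difference clipped at zero.  ``conversion`` rescales both ratios for
    bisulfite non-conversion if it was measured (1.0 = perfect).
    """
    ox = np.asarray(ox_ratio, dtype=float)
    bs = np.asarray(bs_ratio, dtype=float)
    if ((ox < 0) | (ox > 1)).any() or ((bs < 0) | (bs > 1)).any():
        raise ValueError("ratios must lie in [0, 1]")
    if not (0 < conversion <= 1 and 0 < oxidation <= 1):
        raise ValueError("efficiencies must lie in (0, 1]")
    ox = ox / conversion
    bs = bs / conversion
    hmc = np.clip(ox / oxidation, 0.0, 1.0)
    mc = np.maximum(0.0, bs - hmc)
    if hmc.ndim == 0:
        return float(hmc), float(mc)
    return hmc, mc


def read_tabseq(path) -> pd.DataFrame:
    """Read per-CpG counts TSV and compute ratios and levels.

    Required columns: chrom, pos, ox_c, ox_t, bs_c, bs_t (extra columns such
    as sample_id pass through).  Rows with zero depth in either conversion
    are rejected — a ratio is undefined there.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(TABSEQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tabseq table missing columns {sorted(missing)}")
    for col in ["ox_c", "ox_t", "bs_c", "bs_t"]:
        if (df[col] < 0).any():
            raise ValueError(f"negative counts in column {col}")
    ox_depth = df["ox_c"] + df["ox_t"]
    bs_depth = df["bs_c"] + df["bs_t"]
    if (ox_depth == 0).any() or (bs_depth == 0).any():
        bad = df.index[(ox_depth == 0) | (bs_depth == 0)].tolist()
        raise ValueError(f"zero-depth rows at indices {bad[:5]}")
    return add_levels(df)


def add_levels(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["ox_ratio"] = df["ox_c"] / (df["ox_c"] + df["ox_t"])
    df["bs_ratio"] = df["bs_c"] / (df["bs_c"] + df["bs_t"])
    hmc, mc = site_levels(df["ox_ratio"].to_numpy(), df["bs_ratio"].to_numpy())
    df["hmc_level"] = hmc
    df["mc_level"] = mc
    return df


def interval_mean(
    sites: pd.DataFrame, interval: GenomicInterval
) -> tuple[float, float, int]:
    """Unweighted mean 5hmC and 5mC over the CpGs inside an interval."""
    if "hmc_level" not in sites.columns:
        sites = add_levels(sites)
    inside = sites[
        (sites["chrom"] == interval.chrom)
        & (sites["pos"] >= interval.start)
        & (sites["pos"] < interval.end)
    ]
    if len(inside) == 0:
        raise ValueError(f"no CpG sites inside {interval}")
    return (
        float(inside["hmc_level"].mean()),
        float(inside["mc_level"].mean()),
        int(len(inside)),
    )


def concordance(
    block_calls: pd.DataFrame, mean_hmc: pd.DataFrame, call_threshold: float = 0.1
) -> dict[str, int]:
    """Confusion counts between sequencing block calls and TAB-Seq levels.

    Both inputs are sample x interval grids (identical index/columns);
    ``block_calls`` is boolean, ``mean_hmc`` holds interval-averaged 5hmC.
    An entry is TAB-Seq-positive iff mean_hmc >= call_threshold.
    """
    if not block_calls.index.equals(mean_hmc.index) or not block_calls.columns.equals(
        mean_hmc.columns
    ):
        raise ValueError("block_calls and mean_hmc grids do not match")
    ngs = block_calls.to_numpy(dtype=bool)
    tab = mean_hmc.to_numpy(dtype=float) >= call_threshold
    return {
        "TP": int((ngs & tab).sum()),
        "FP": int((ngs & ~tab).sum()),
        "FN": int((~ngs & tab).sum()),
        "TN": int((~ngs & ~tab).sum()),
    }
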