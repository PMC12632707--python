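"""Sliding-window chi-squared caller for differentially methylated regions.

The procedure, applied per contrast (one exposed group vs one control
group, replicates pooled):

1. tile each chromosome into fixed-width windows (200 bp by default,
   non-overlapping; the step is configurable and overlapping windows are
   handled by the merge stage);
2. keep CpG sites whose pooled read coverage reaches ``site_min_coverage``
   in *both* groups (20 reads by default);
3. per window, sum methylated / unmethylated reads over retained sites and
   replicates into a 2x2 table and apply the uncorrected Pearson
   chi-squared test; windows with no retained site or a zero marginal are
   untestable and never enter the multiple-testing correction;
4. Benjamini-Hochberg over all testable windows genome-wide; a window is
   significant iff q < ``max_q``, |Δβ| >= ``min_delta``, it holds at least
   ``region_min_cpgs`` CpGs, and per-group mean coverage over its retained
   CpGs reaches ``region_min_avg_coverage``;
5. merge neighbouring significant windows (gap <= ``merge_max_gap``,
   same direction required by default) and recompute the span-level
   methylation levels from the pooled counts of the merged span.

β values are always pooled ratios, methylated / (methylated +
unmethylated); Δβ = exposed − control; *hyper* means exposed > control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import merge_regions
from .stats import bh_adjust, chi2_sf_df1

__all__ = [
    "DmrParams",
    "tile_genome",
    "pool_groups",
    "filter_sites",
    "score_windows",
    "call_dmrs",
]


@dataclass
class DmrParams:
    """Tunable constants of the DMR caller.

    Defaults are the study thresholds: 200 bp windows, 20x pooled coverage
    per site and per region on average, >= 2 CpGs, |Δβ| >= 0.1, BH q < 0.1,
    bookended same-direction merging.
    """

    window_size: int = 200
    window_step: int = 200
    site_min_coverage: int = 20
    region_min_cpgs: int = 2
    region_min_avg_coverage: float = 20.0
    min_delta: float = 0.1
    max_q: float = 0.1
    merge_max_gap: int = 0
    require_same_direction: bool = True
    yates_correction: bool = False  # kept off: plain Pearson chi-squared

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be > 0")
        if not (0 < self.window_step <= self.window_size):
            raise ValueError("require 0 < window_step <= window_size")
        if not (0 < self.min_delta <= 1):
            raise ValueError("min_delta must lie in (0, 1]")
        if not (0 < self.max_q <= 1):
            raise ValueError("max_q must lie in (0, 1]")
        if self.merge_max_gap < 0 or self.site_min_coverage < 0:
            raise ValueError("negative threshold")


def tile_genome(chrom_sizes: Mapping[str, int], params: DmrParams) -> pd.DataFrame:
    """Ordered fixed-width windows over every chromosome.

    Windows are ``[k*step, k*step + size)`` clipped at the chromosome end;
    a non-empty terminal partial window is kept.
    """
    frames = []
    for chrom, length in chrom_sizes.items():
        if length < 0:
            raise ValueError(f"negative length for {chrom}")
        if length == 0:
            warnings.warn(f"chromosome {chrom} has zero length: no windows")
            continue
        starts = np.arange(0, length, params.window_step, dtype=np.int64)
        ends = np.minimum(starts + params.window_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    return pd.concat(frames, ignore_index=True)


def pool_groups(
    samples: Mapping[str, pd.DataFrame], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Sum per-CpG methylated/unmethylated counts over replicates per group.

    ``samples`` maps sample id -> cytosine table (chrom, pos, meth, unmeth);
    ``groups`` maps sample id -> ``'control'`` or ``'exposed'``.  Returns one
    row per CpG seen in any sample, sorted by (chrom, pos), with columns
    ``meth_control``, ``unmeth_control``, ``meth_exposed``, ``unmeth_exposed``.
    """
    for g in ("control", "exposed"):
        if not any(v == g for v in groups.values()):
            raise ValueError(f"no samples assigned to group {g!r}")
    unknown = {s: g for s, g in groups.items() if g not in ("control", "exposed")}
    if unknown:
        raise ValueError(f"unknown group labels: {unknown}")
    parts = []
    for sample, df in samples.items():
        g = groups[sample]
        part = df.loc[:, ["chrom", "pos", "meth", "unmeth"]].copy()
        part["group"] = g
        parts.append(part)
    allrec = pd.concat(parts, ignore_index=True)
    pooled = (
        allrec.groupby(["chrom", "pos", "group"], sort=True)[["meth", "unmeth"]]
        .sum()
        .unstack("group", fill_value=0)
    )
    pooled.columns = [f"{m}_{g}" for m, g in pooled.columns]
    for col in ("meth_control", "unmeth_control", "meth_exposed", "unmeth_exposed"):
        if col not in pooled.columns:
            pooled[col] = 0
    pooled = pooled.reset_index().sort_values(["chrom", "pos"], kind="mergesort")
    return pooled.reset_index(drop=True)


def filter_sites(pooled: pd.DataFrame, params: DmrParams) -> pd.DataFrame:
    """Retain CpGs with pooled coverage >= ``site_min_coverage`` in both groups."""
    cov_c = pooled["meth_control"] + pooled["unmeth_control"]
    cov_e = pooled["meth_exposed"] + pooled["unmeth_exposed"]
    keep = (cov_c >= params.site_min_coverage) & (cov_e >= params.site_min_coverage)
    if params.site_min_coverage == 0:
        keep = (cov_c + cov_e) > 0
    return pooled.loc[keep].reset_index(drop=True)


def _window_sums(windows: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Per-window sums of retained-site counts via searchsorted per chromosome."""
    cols = ["meth_control", "unmeth_control", "meth_exposed", "unmeth_exposed"]
    out = np.zeros((len(windows), len(cols)), dtype=np.int64)
    n_cpgs = np.zeros(len(windows), dtype=np.int64)
    for chrom, widx in windows.groupby("chrom").groups.items():
        g = sites.loc[sites["chrom"] == chrom]
        if not len(g):
            continue
        pos = g["pos"].to_numpy(np.int64)
        cum = np.vstack([np.concatenate([[0], np.cumsum(g[c].to_numpy(np.int64))])
                         for c in cols]).T  # (n+1, 4)
        w = windows.loc[widx]
        lo = np.searchsorted(pos, w["start"].to_numpy(np.int64), side="left")
        hi = np.searchsorted(pos, w["end"].to_numpy(np.int64), side="left")
        rows = windows.index.get_indexer(widx)
        out[rows] = cum[hi] - cum[lo]
        n_cpgs[rows] = hi - lo
    res = windows.loc[:, ["chrom", "start", "end"]].copy()
    res["n_cpgs"] = n_cpgs
    for j, c in enumerate(cols):
        res[c] = out[:, j]
    return res


def score_windows(windows: pd.DataFrame, sites: pd.DataFrame,
                  params: DmrParams) -> pd.DataFrame:
    """Pool counts per window, test each 2x2 table, and BH-adjust.

    Returns one row per window with β per group, Δβ, chi2, p, q, a
    ``testable`` flag (retained CpGs present and all four marginals > 0) and
    mean pooled coverage per group.  Untestable windows carry NaN
    statistics and are excluded from the BH adjustment.
    """
    ws = _window_sums(windows, sites)
    mc = ws["meth_control"].to_numpy(float)
    uc = ws["unmeth_control"].to_numpy(float)
    me = ws["meth_exposed"].to_numpy(float)
    ue = ws["unmeth_exposed"].to_numpy(float)
    r1, r2 = mc + uc, me + ue
    c1, c2 = mc + me, uc + ue
    testable = (ws["n_cpgs"].to_numpy() > 0) & (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    n = r1 + r2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (mc * ue - uc * me) ** 2 / (r1 * r2 * c1 * c2)
        if params.yates_correction:
            adj = np.maximum(np.abs(mc * ue - uc * me) - n / 2.0, 0.0)
            stat = n * adj**2 / (r1 * r2 * c1 * c2)
        beta_c = mc / r1
        beta_e = me / r2
        cov_c = np.where(ws["n_cpgs"] > 0, r1 / np.maximum(ws["n_cpgs"], 1), 0.0)
        cov_e = np.where(ws["n_cpgs"] > 0, r2 / np.maximum(ws["n_cpgs"], 1), 0.0)
    stat = np.where(testable, stat, np.nan)
    p = np.full(len(ws), np.nan)
    p[testable] = chi2_sf_df1(stat[testable])
    q = np.full(len(ws), np.nan)
    if testable.any():
        q[testable] = bh_adjust(p[testable])
    ws["beta_control"] = np.where(testable, beta_c, np.nan)
    ws["beta_exposed"] = np.where(testable, beta_e, np.nan)
    ws["delta"] = ws["beta_exposed"] - ws["beta_control"]
    ws["mean_cov_control"] = cov_c
    ws["mean_cov_exposed"] = cov_e
    ws["chi2"] = stat
    ws["p"] = p
    ws["q"] = q
    ws["testable"] = testable
    return ws


def call_dmrs(
    samples: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    chrom_sizes: Mapping[str, int],
    params: DmrParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full window caller and return (window table, DMR table).

    The DMR table has one row per merged region: chrom/start/end,
    ``direction`` (hyper/hypo, exposed relative to control), n_cpgs and
    pooled β/Δβ recomputed over the merged span, the minimum constituent
    window q, and the number of constituent windows.
    """
    params = params or DmrParams()
    pooled = pool_groups(samples, groups)
    sites = filter_sites(pooled, params)
    windows = tile_genome(chrom_sizes, params)
    if not len(windows):
        warnings.warn("no windows: empty genome")
        return _empty_windows(), _empty_dmrs()
    ws = score_windows(windows, sites, params)
    if not ws["testable"].any():
        warnings.warn("no testable windows")
        ws["significant"] = False
        return ws, _empty_dmrs()
    # the delta threshold is inclusive; compare with a 1e-12 slack so that a
    # window at exactly the threshold is not lost to float subtraction
    sig = (
        ws["testable"]
        & (ws["q"] < params.max_q)
        & (ws["delta"].abs() >= params.min_delta - 1e-12)
        & (ws["n_cpgs"] >= params.region_min_cpgs)
        & (ws["mean_cov_control"] >= params.region_min_avg_coverage)
        & (ws["mean_cov_exposed"] >= params.region_min_avg_coverage)
    )
    ws["significant"] = sig
    ws["direction"] = np.where(ws["delta"] > 0, "hyper", "hypo")
    ws.loc[~ws["testable"], "direction"] = pd.NA
    sigw = ws.loc[sig]
    if not len(sigw):
        return ws, _empty_dmrs()
    merged = merge_regions(
        sigw.loc[:, ["chrom", "start", "end", "direction"]],
        max_gap=params.merge_max_gap,
        require_same_direction=params.require_same_direction,
    )
    records = []
    for _, row in merged.iterrows():
        span_sites = sites.loc[
            (sites["chrom"] == row["chrom"])
            & (sites["pos"] >= row["start"])
            & (sites["pos"] < row["end"])
        ]
        mc = int(span_sites["meth_control"].sum())
        uc = int(span_sites["unmeth_control"].sum())
        me = int(span_sites["meth_exposed"].sum())
        ue = int(span_sites["unmeth_exposed"].sum())
        beta_c = mc / (mc + uc)
        beta_e = me / (me + ue)
        delta = beta_e - beta_c
        members = row["members"]
        direction = row["direction"] if params.require_same_direction else (
            "hyper" if delta > 0 else "hypo"
        )
        records.append(
            {
                "chrom": row["chrom"],
                "start": int(row["start"]),
                "end": int(row["end"]),
                "direction": direction,
                "n_cpgs": int(len(span_sites)),
                "beta_control": beta_c,
                "beta_exposed": beta_e,
                "delta": delta,
                "min_q": float(sigw.loc[members, "q"].min()),
                "n_windows": len(members),
            }
        )
    dmrs = pd.DataFrame(records)
    # merging can in principle dilute the span-level |Δβ| below the window
    # threshold; such spans would violate the caller's own contract, so drop
    dmrs = dmrs.loc[dmrs["delta"].abs() >= params.min_delta - 1e-12]
    dmrs = dmrs.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    return ws, dmrs


def _empty_windows() -> pd.DataFrame:
    cols = ["chrom", "start", "end", "n_cpgs", "meth_control", "unmeth_control",
            "meth_exposed", "unmeth_exposed", "beta_control", "beta_exposed",
            "delta", "mean_cov_control", "mean_cov_exposed", "chi2", "p", "q",
            "testable", "significant"]
    return pd.DataFrame(columns=cols)


def _empty_dmrs() -> pd.DataFrame:
    cols = ["chrom", "start", "end", "direction", "n_cpgs", "beta_control",
            "beta_exposed", "delta", "min_q", "n_windows"]
    return pd.DataFrame(columns=cols)


def dmr_bed_frame(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6+ view of a DMR table: name = direction, score = -log10(min q)."""
    if not len(dmrs):
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score",
                                     "strand", "n_cpgs", "beta_control",
                                     "beta_exposed", "delta"])
    score = -np.log10(np.maximum(dmrs["min_q"].to_numpy(float), 1e-300))
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["direction"],
            "score": np.round(score, 4),
            "strand": ".",
            "n_cpgs": dmrs["n_cpgs"],
            "beta_control": dmrs["beta_control"].round(6),
            "beta_exposed": dmrs["beta_exposed"].round(6),
            "delta": dmrs["delta"].round(6),
        }
    )
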