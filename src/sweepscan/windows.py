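"""Kernel-smoothed sliding-window genome scan with bootstrap outlier calling.

Windows live on genetic-map (centimorgan) coordinates: by default 0.15 cM
windows advanced in 0.03 cM steps along each linkage group.  Per-site F_ST
and subpopulation pi values are smoothed into window means (uniform kernel by
default; a truncated Gaussian kernel with sigma = window/3 is available), the
window pi ratio is the ratio of the two smoothed pi means, and window
significance comes from a bootstrap null: for a window holding k SNPs, the
null distribution is the mean of k per-site values resampled with replacement
from the genome-wide pool, upper tail.  Runs of significant windows are
merged into candidate sweep regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GeneticMap

logger = logging.getLogger(__name__)

STATISTICS = ("fst", "pi_ratio")


@dataclass(frozen=True)
class ScanConfig:
    """Window-scan parameters.

    window_cm / step_cm : float
        Sliding-window width and step, centimorgan.
    alpha : float
        Bootstrap significance threshold (upper tail).
    n_boot : int
        Bootstrap replicates per statistic and per window SNP count.
    kernel : {"uniform", "gaussian"}
        Uniform kernel takes the unweighted mean of sites in the window;
        the Gaussian option weights by a truncated normal with
        sigma = window_cm / 3.
    """

    window_cm: float = 0.15
    step_cm: float = 0.03
    alpha: float = 0.05
    n_boot: int = 1_000_000
    kernel: str = "uniform"

    def __post_init__(self) -> None:
        if self.window_cm <= 0:
            raise ValueError("window_cm must be > 0")
        if not 0 < self.step_cm <= self.window_cm:
            raise ValueError("need 0 < step_cm <= window_cm")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.kernel not in ("uniform", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass(frozen=True)
class GenomeSpec:
    """Genome-scale constants for converting map lengths to physical scale."""

    total_map_length_cm: float = 837.11
    genome_size_mb: float = 630.0

    def __post_init__(self) -> None:
        if self.total_map_length_cm <= 0 or self.genome_size_mb <= 0:
            raise ValueError("genome constants must be positive")


def make_windows(gmap: GeneticMap, cfg: ScanConfig) -> pd.DataFrame:
    """Window centres per linkage group.

    Centres run from the group's minimum position in ``step_cm`` increments
    until they reach or pass the maximum position; each window spans the
    half-open interval [centre - w/2, centre + w/2).
    """
    rows = []
    for lg in gmap.groups:
        lo, hi = gmap.group_span(lg)
        n_steps = int(np.ceil(round((hi - lo) / cfg.step_cm, 9)))
        centers = lo + cfg.step_cm * np.arange(n_steps + 1)
        for c in centers:
            rows.append((lg, float(c)))
    w = pd.DataFrame(rows, columns=["lg", "center_cm"])
    w["start_cm"] = w["center_cm"] - cfg.window_cm / 2
    w["end_cm"] = w["center_cm"] + cfg.window_cm / 2
    return w


def smooth_statistic(
    sites: pd.DataFrame,
    windows: pd.DataFrame,
    cfg: ScanConfig,
    value_cols: tuple[str, ...] = ("fst", "pi_pop1", "pi_pop2"),
) -> pd.DataFrame:
    """Kernel-smoothed window means of per-site values.

    ``sites`` needs columns ``lg``, ``cm`` and each of ``value_cols`` (finite,
    post-substitution).  Returns the windows with SNP count ``k`` and a
    ``<col>_mean`` per value column (NaN when k = 0), plus the window pi
    ratio ``pi_ratio`` = pi_pop1_mean / pi_pop2_mean (NaN when the
    denominator is zero or the window is empty).
    """
    out = windows.copy()
    k = np.zeros(len(out), dtype=int)
    means = {c: np.full(len(out), np.nan) for c in value_cols}

    for lg, wsub in out.groupby("lg"):
        ssub = sites[sites["lg"] == lg].sort_values("cm")
        pos = ssub["cm"].to_numpy()
        widx = wsub.index.to_numpy()
        lo = np.searchsorted(pos, wsub["start_cm"].to_numpy(), side="left")
        hi = np.searchsorted(pos, wsub["end_cm"].to_numpy(), side="left")
        k[widx] = hi - lo
        if cfg.kernel == "uniform":
            for c in value_cols:
                vals = ssub[c].to_numpy(dtype=float)
                csum = np.concatenate([[0.0], np.cumsum(vals)])
                with np.errstate(invalid="ignore", divide="ignore"):
                    m = (csum[hi] - csum[lo]) / (hi - lo)
                means[c][widx] = m
        else:  # gaussian, truncated at the window span
            sigma = cfg.window_cm / 3.0
            centers = wsub["center_cm"].to_numpy()
            for i, (a, b, c0) in enumerate(zip(lo, hi, centers)):
                if a == b:
                    continue
                wgt = np.exp(-0.5 * ((pos[a:b] - c0) / sigma) ** 2)
                for c in value_cols:
                    vals = ssub[c].to_numpy(dtype=float)[a:b]
                    means[c][widx[i]] = np.sum(wgt * vals) / np.sum(wgt)

    out["k"] = k
    for c in value_cols:
        out[f"{c}_mean"] = means[c]
    if {"pi_pop1", "pi_pop2"} <= set(value_cols):
        out["pi_ratio"] = window_pi_ratio(out["pi_pop1_mean"], out["pi_pop2_mean"])
    return out


def window_pi_ratio(pi1_mean, pi2_mean):
    """Window diversity ratio pi1/pi2; NaN where the denominator is zero.

    Large values flag diversity loss in subpopulation 2 (candidate sweep).
    Undefined ratios are excluded from ranking rather than substituted.
    """
    pi1 = np.asarray(pi1_mean, dtype=float)
    pi2 = np.asarray(pi2_mean, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = pi1 / pi2
    return np.where(pi2 == 0, np.nan, r)[()]


def bootstrap_pvalues(
    sites: pd.DataFrame,
    windows: pd.DataFrame,
    cfg: ScanConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Upper-tail bootstrap p-values for window F_ST means and pi ratios.

    For every distinct SNP count k among the windows, ``cfg.n_boot``
    replicates are drawn, each the mean of k sites resampled with replacement
    from the genome-wide pool of per-site values; for the pi ratio a replicate
    resamples k (pi1, pi2) site pairs and takes the ratio of the two means.
    p = (1 + #{replicate >= observed}) / (1 + n_boot).  Replicates are banked
    per k and shared by every window with that k, which also makes the result
    invariant to window order; the draw sequence is fixed by ``seed``.
    """
    fst_pool = sites["fst"].to_numpy(dtype=float)
    pi1_pool = sites["pi_pop1"].to_numpy(dtype=float)
    pi2_pool = sites["pi_pop2"].to_numpy(dtype=float)
    if len(fst_pool) < 2:
        raise ValueError("per-site pool too small to bootstrap")
    if not np.isfinite(fst_pool).all():
        raise ValueError("per-site F_ST pool contains non-finite values; "
                         "substitute undefined sites first")

    out = windows.copy()
    out["p_fst"] = np.nan
    out["p_ratio"] = np.nan
    occupied = out[out["k"] > 0]
    rng = np.random.default_rng(seed)
    npool = len(fst_pool)
    max_chunk = 2_000_000  # index draws held at once

    for k in sorted(occupied["k"].unique()):
        rows = occupied[occupied["k"] == k]
        obs_f = rows["fst_mean"].to_numpy(dtype=float)
        obs_r = rows["pi_ratio"].to_numpy(dtype=float)
        ge_f = np.zeros(len(rows), dtype=np.int64)
        ge_r = np.zeros(len(rows), dtype=np.int64)
        remaining = cfg.n_boot
        rows_per_chunk = max(1, max_chunk // int(k))
        while remaining > 0:
            m = min(remaining, rows_per_chunk)
            idx = rng.integers(0, npool, size=(m, int(k)))
            rep_f = fst_pool[idx].mean(axis=1)
            s1 = pi1_pool[idx].mean(axis=1)
            s2 = pi2_pool[idx].mean(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                rep_r = np.where(s2 > 0, s1 / s2, np.inf)
            rep_f.sort()
            rep_r.sort()
            ge_f += m - np.searchsorted(rep_f, obs_f, side="left")
            ge_r += m - np.searchsorted(rep_r, obs_r, side="left")
            remaining -= m
        out.loc[rows.index, "p_fst"] = (1 + ge_f) / (1 + cfg.n_boot)
        # windows with undefined ratio keep NaN p
        defined = np.isfinite(obs_r)
        p_r = np.where(defined, (1 + ge_r) / (1 + cfg.n_boot), np.nan)
        out.loc[rows.index, "p_ratio"] = p_r

    out["sig_fst"] = out["p_fst"] <= cfg.alpha
    out["sig_ratio"] = out["p_ratio"] <= cfg.alpha
    return out


@dataclass
class RegionTotals:
    """Summed sweep-region length per statistic, in cM.

    ``window_extent`` measures each region as the union of member window
    spans (clipped to the linkage group); ``center_span`` measures it as the
    distance between the first and last member window centres.
    """

    window_extent: dict = field(default_factory=dict)
    center_span: dict = field(default_factory=dict)


def call_outlier_regions(
    windows: pd.DataFrame,
    cfg: ScanConfig,
    gmap: GeneticMap,
) -> tuple[pd.DataFrame, RegionTotals]:
    """Merge significant windows into candidate sweep regions.

    Windows with p <= alpha are significant; overlapping or abutting
    significant windows on the same linkage group merge into one region whose
    span is the union of member window spans clipped to [group min,
    group max].  Returns a region table (lg, start_cm, end_cm, statistic,
    length_cm, n_windows, center_start_cm, center_end_cm) and the summed
    length per statistic, reported both as window-extent union and as
    centre-to-centre span.
    """
    regions = []
    totals = RegionTotals()
    for stat, flag in (("fst", "sig_fst"), ("pi_ratio", "sig_ratio")):
        total_ext = 0.0
        total_ctr = 0.0
        for lg, sub in windows.groupby("lg"):
            lo, hi = gmap.group_span(lg)
            sig = sub[sub[flag].fillna(False)].sort_values("center_cm")
            if sig.empty:
                continue
            start = np.maximum(sig["start_cm"].to_numpy(), lo)
            end = np.minimum(sig["end_cm"].to_numpy(), hi)
            centers = sig["center_cm"].to_numpy()
            cur = [start[0], end[0], centers[0], centers[0], 1]
            merged = []
            for s, e, c in zip(start[1:], end[1:], centers[1:]):
                if s <= cur[1]:  # overlap or abut
                    cur[1] = max(cur[1], e)
                    cur[3] = c
                    cur[4] += 1
                else:
                    merged.append(tuple(cur))
                    cur = [s, e, c, c, 1]
            merged.append(tuple(cur))
            for s, e, c0, c1, nw in merged:
                regions.append(
                    {
                        "lg": lg,
                        "start_cm": s,
                        "end_cm": e,
                        "statistic": stat,
                        "length_cm": e - s,
                        "n_windows": nw,
                        "center_start_cm": c0,
                        "center_end_cm": c1,
                    }
                )
                total_ext += e - s
                total_ctr += c1 - c0
        totals.window_extent[stat] = total_ext
        totals.center_span[stat] = total_ctr
    cols = ["lg", "start_cm", "end_cm", "statistic", "length_cm",
            "n_windows", "center_start_cm", "center_end_cm"]
    return pd.DataFrame(regions, columns=cols), totals


def genome_fraction(total_length_cm: float, spec: GenomeSpec) -> float:
    """Percent of the genetic map covered by ``total_length_cm``."""
    if total_length_cm < 0:
        raise ValueError("length must be >= 0")
    return 100.0 * total_length_cm / spec.total_map_length_cm


def cm_to_kb(distance_cm: float, spec: GenomeSpec) -> float:
    """Convert a genetic distance to an approximate physical distance (Kb)
    using the genome-wide average Kb-per-cM ratio."""
    if distance_cm < 0:
        raise ValueError("distance must be >= 0")
    return distance_cm * (spec.genome_size_mb * 1000.0) / spec.total_map_length_cm
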