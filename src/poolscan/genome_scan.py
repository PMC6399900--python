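"""Per-site and sliding-window diversity/differentiation statistics.

The differentiation statistic is Hudson-style
``F_ST = 1 − π_W/π_B``, where π_W is the mean of the two species'
within-pool nucleotide diversity and π_B the mean pairwise divergence
between pools.  Window-level F_ST is the ratio of window-summed π's (ratio
of averages), which is robust to low-information sites; negative values are
retained throughout (no clamping), matching the slight negative skew seen
when two samples come from one panmictic population.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import GenomeTable
from .poolseq_inference import PoolModel, ml_frequency_lookup

logger = logging.getLogger("poolscan")

__all__ = ["site_pi_within", "site_pi_between", "fst_value",
           "per_site_fst", "scan_windows", "fst_by_coverage_bins"]


def site_pi_within(p_hat, n: int):
    """Within-pool heterozygosity [n/(n−1)]·2p(1−p) at one site."""
    if n < 2:
        raise ValueError("need n >= 2")
    p = np.asarray(p_hat, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("frequency must be in [0, 1]")
    out = (n / (n - 1)) * 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def site_pi_between(p1, p2):
    """Between-pool pairwise divergence p1(1−p2) + p2(1−p1)."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    out = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return float(out) if out.ndim == 0 else out


def fst_value(pi_w, pi_b):
    """1 − π_W/π_B; NaN where π_B = 0 (undefined), negatives retained."""
    pi_w = np.asarray(pi_w, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pi_b > 0, 1.0 - pi_w / pi_b, np.nan)
    return float(out) if out.ndim == 0 else out


def per_site_fst(p1, p2, n: int):
    """Vectorised per-site F_ST from the two pools' frequency estimates."""
    pw = 0.5 * (site_pi_within(p1, n) + site_pi_within(p2, n))
    pb = site_pi_between(p1, p2)
    return fst_value(pw, pb)


def _estimate_freqs(table: GenomeTable, model: PoolModel
                    ) -> tuple[np.ndarray, np.ndarray]:
    df = table.df
    max_r = int(max(df["r1"].max(), df["r2"].max()))
    lut = ml_frequency_lookup(max_r, model)
    p1 = lut[df["r1"].to_numpy(), df["k1"].to_numpy()] / model.n
    p2 = lut[df["r2"].to_numpy(), df["k2"].to_numpy()] / model.n
    return p1, p2


def scan_windows(table: GenomeTable, model: PoolModel | None = None,
                 window: int = 10_000, step: int = 5_000,
                 min_cov_fraction: float = 0.5,
                 min_coverage: int = 20) -> pd.DataFrame:
    """Sliding-window π_W, π_B and F_ST over a (filtered) site table.

    Windows tile each chromosome at multiples of ``step`` (0-based starts),
    fixed width ``window``; a window is reported only if it contains at
    least one site and at least ``min_cov_fraction`` of its sites have
    ``>= min_coverage`` reads in both species.  Per-window π's are the
    per-covered-site averages; F_ST is computed from the window π's.

    Returns a DataFrame with columns
    ``chrom, start, end, n_sites, pi_w, pi_b, fst``.
    """
    if model is None:
        model = PoolModel(n=table.n_pool[0], epsilon=table.epsilon)
    if window < step:
        logger.warning("window (%d) < step (%d): windows leave gaps",
                       window, step)
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    bins_per_window = window // step

    if len(table) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                     "pi_w", "pi_b", "fst"])

    df = table.df
    p1, p2 = _estimate_freqs(table, model)
    n = model.n
    piw_site = 0.5 * (site_pi_within(p1, n) + site_pi_within(p2, n))
    pib_site = site_pi_between(p1, p2)
    covered = ((df["r1"].to_numpy() >= min_coverage)
               & (df["r2"].to_numpy() >= min_coverage))

    out = []
    pos0 = df["pos"].to_numpy() - 1  # 0-based
    chroms = df["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        cpos = pos0[sel]
        cw, cb = piw_site[sel], pib_site[sel]
        cov = covered[sel]
        n_bins = int(cpos.max() // step) + 1
        binidx = cpos // step
        sums_w = np.bincount(binidx, weights=np.where(cov, cw, 0.0),
                             minlength=n_bins)
        sums_b = np.bincount(binidx, weights=np.where(cov, cb, 0.0),
                             minlength=n_bins)
        n_sites = np.bincount(binidx, minlength=n_bins)
        n_cov = np.bincount(binidx, weights=cov.astype(float),
                            minlength=n_bins)

        def roll(a):
            c = np.concatenate([[0.0], np.cumsum(a)])
            return c[bins_per_window:] - c[:-bins_per_window]

        n_starts = n_bins - bins_per_window + 1
        if n_starts < 1:
            continue
        w_sum, b_sum = roll(sums_w), roll(sums_b)
        s_tot, s_cov = roll(n_sites.astype(float)), roll(n_cov)
        starts = np.arange(n_starts) * step
        with np.errstate(invalid="ignore", divide="ignore"):
            keep = (s_tot > 0) & (s_cov >= min_cov_fraction * s_tot)
            pi_w = np.where(s_cov > 0, w_sum / s_cov, np.nan)
            pi_b = np.where(s_cov > 0, b_sum / s_cov, np.nan)
        fst = fst_value(pi_w, pi_b)
        sub = pd.DataFrame({
            "chrom": chrom,
            "start": starts[keep],
            "end": starts[keep] + window,
            "n_sites": s_cov[keep].astype(int),
            "pi_w": pi_w[keep],
            "pi_b": pi_b[keep],
            "fst": fst[keep],
        })
        out.append(sub)
    if not out:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                     "pi_w", "pi_b", "fst"])
    return pd.concat(out, ignore_index=True)


def fst_by_coverage_bins(fst: np.ndarray, cov1: np.ndarray,
                         cov2: np.ndarray,
                         edges: np.ndarray | None = None) -> pd.DataFrame:
    """Mean ± 1 SD of per-site F_ST per coverage bin.

    A site's bin is determined by the smaller of its two coverages; default
    bins are width 10 spanning the observed coverage range.  Returns columns
    ``bin_left, bin_right, mean, sd, n`` (sample SD; NaN F_ST dropped).
    """
    fst = np.asarray(fst, dtype=float)
    cov = np.minimum(np.asarray(cov1), np.asarray(cov2)).astype(float)
    ok = ~np.isnan(fst)
    fst, cov = fst[ok], cov[ok]
    if len(fst) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right",
                                     "mean", "sd", "n"])
    if edges is None:
        lo = 10 * int(cov.min() // 10)
        hi = 10 * int(cov.max() // 10) + 10
        edges = np.arange(lo, hi + 1, 10)
    edges = np.asarray(edges, dtype=float)
    idx = np.digitize(cov, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        vals = fst[idx == b]
        if len(vals) == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append((edges[b], edges[b + 1], float(vals.mean()),
                     sd, len(vals)))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right",
                                       "mean", "sd", "n"])
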