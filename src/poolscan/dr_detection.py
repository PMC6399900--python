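"""Screening of top-quantile windows and calling of differentiated regions.

A differentiated region (DR) is a run of merged sliding windows whose F_ST
exceeds the top-quantile screening threshold, that looks like an isolated
peak (the windows flanking the merged span sit below the genome-wide
background quantile) and that contains at least one fixed nucleotide
difference between the species.  Significance against a simulated panmixia
null and a simple expected-false-positives FDR estimate can be attached per
window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomeTable
from .poolseq_inference import PoolModel, ml_frequency_lookup

__all__ = ["DifferentiatedRegion", "fst_threshold_top_quantile",
           "find_fixed_differences", "call_differentiated_regions",
           "window_neutrality_pvalue", "estimate_fdr"]


@dataclass
class DifferentiatedRegion:
    chrom: str
    start: int  # 0-based half-open
    end: int
    member_windows: list = field(default_factory=list)  # (start, end, fst)
    max_fst: float = 0.0
    fixed_diff_positions: list = field(default_factory=list)  # 1-based
    p_value: float | None = None
    fdr: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("DR must have positive length")

    @property
    def length(self) -> int:
        return self.end - self.start


def fst_threshold_top_quantile(window_fsts, q: float = 0.001) -> float:
    """Empirical (1−q) quantile such that strictly greater values are in
    the top-q fraction; ties with the threshold are excluded.

    q = 0 returns +inf (nothing selected).  NaN windows are ignored.
    """
    vals = np.asarray(window_fsts, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no window F_ST values")
    if q == 0:
        return float("inf")
    if not 0 < q <= 1:
        raise ValueError("q must be in [0, 1]")
    if len(vals) < 1 / q:
        warnings.warn(f"only {len(vals)} windows for top-{q:g} screening; "
                      "threshold is poorly resolved", stacklevel=2)
    return float(np.quantile(vals, 1.0 - q, method="lower"))


def find_fixed_differences(table: GenomeTable, model: PoolModel | None = None,
                           min_cov: int = 20) -> pd.DataFrame:
    """Sites whose ML allele counts are at opposite boundaries (ŷ = n in one
    species, 0 in the other), with coverage >= min_cov in both species.

    Returns a DataFrame ``chrom, pos`` (1-based positions).
    """
    if model is None:
        model = PoolModel(n=table.n_pool[0], epsilon=table.epsilon)
    df = table.df
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "pos"])
    ok = ((df["r1"].to_numpy() >= min_cov)
          & (df["r2"].to_numpy() >= min_cov))
    sub = df.loc[ok]
    if len(sub) == 0:
        return pd.DataFrame(columns=["chrom", "pos"])
    lut = ml_frequency_lookup(int(max(sub["r1"].max(), sub["r2"].max())),
                              model)
    y1 = lut[sub["r1"].to_numpy(), sub["k1"].to_numpy()]
    y2 = lut[sub["r2"].to_numpy(), sub["k2"].to_numpy()]
    n = model.n
    fixed = ((y1 == n) & (y2 == 0)) | ((y1 == 0) & (y2 == n))
    return (sub.loc[fixed, ["chrom", "pos"]]
            .reset_index(drop=True))


def call_differentiated_regions(windows: pd.DataFrame, threshold: float,
                                fixed_diffs: pd.DataFrame,
                                background_quantile: float = 0.9,
                                flank_windows: int = 3
                                ) -> list[DifferentiatedRegion]:
    """Merge top windows into peaks and keep those with fixed differences.

    Procedure: (1) select windows with F_ST strictly above ``threshold``;
    (2) merge selected windows whose spans overlap or abut into candidate
    peaks; (3) peak-shape test: on each side of the merged span, F_ST must
    return to background within ``flank_windows`` windows — the minimum
    F_ST over the nearest ``flank_windows`` windows entirely outside the
    span must lie below the ``background_quantile`` of all window values
    (a single window is a noisy estimate, so one elevated neighbour does
    not disqualify a peak, but a broad plateau does); (4) require >= 1
    fixed difference inside the span.  The DR interval is the union of its
    member windows.
    """
    fsts = windows["fst"].to_numpy(dtype=float)
    bg_value = float(np.nanquantile(fsts, background_quantile))
    fd_by_chrom: dict[str, np.ndarray] = {
        str(c): np.sort(g["pos"].to_numpy())
        for c, g in fixed_diffs.groupby("chrom", observed=True)
    } if len(fixed_diffs) else {}

    drs: list[DifferentiatedRegion] = []
    for chrom, sub in windows.groupby("chrom", sort=False, observed=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        wfst = sub["fst"].to_numpy(dtype=float)
        sel = np.flatnonzero(wfst > threshold)
        if len(sel) == 0:
            continue
        # merge overlapping/abutting selected windows
        blocks: list[list[int]] = [[sel[0]]]
        for i in sel[1:]:
            if starts[i] <= ends[blocks[-1][-1]]:
                blocks[-1].append(i)
            else:
                blocks.append([i])
        fd_pos = fd_by_chrom.get(str(chrom), np.empty(0, dtype=np.int64))
        for block in blocks:
            span_start = int(starts[block[0]])
            span_end = int(max(ends[i] for i in block))
            # peak shape: F_ST must return to background within
            # flank_windows windows fully outside the span on each side
            left = np.flatnonzero(ends <= span_start)[-flank_windows:]
            right = np.flatnonzero(starts >= span_end)[:flank_windows]
            flank_ok = True
            for side in (left, right):
                vals = wfst[side]
                vals = vals[~np.isnan(vals)]
                if len(vals):
                    flank_ok &= bool(vals.min() < bg_value)
            if not flank_ok:
                continue
            # 1-based positions p inside [span_start, span_end) 0-based
            inside = fd_pos[(fd_pos - 1 >= span_start)
                            & (fd_pos - 1 < span_end)]
            if len(inside) == 0:
                continue
            drs.append(DifferentiatedRegion(
                chrom=str(chrom), start=span_start, end=span_end,
                member_windows=[(int(starts[i]), int(ends[i]),
                                 float(wfst[i])) for i in block],
                max_fst=float(max(wfst[i] for i in block)),
                fixed_diff_positions=[int(p) for p in inside],
            ))
    for i, dr in enumerate(drs):
        dr.name = f"DR{i + 1}"
    return drs


def window_neutrality_pvalue(observed_fst: float, null_fsts) -> float:
    """Add-one empirical p-value (1 + #{null >= obs}) / (1 + #null)."""
    null = np.asarray(null_fsts, dtype=float)
    null = null[~np.isnan(null)]
    if len(null) == 0:
        raise ValueError("empty null distribution")
    return float((1 + np.count_nonzero(null >= observed_fst))
                 / (1 + len(null)))


def estimate_fdr(p_value: float, n_windows_tested: int,
                 n_selected: int) -> float:
    """Expected false positives over discoveries: min(1, p·M/k)."""
    if n_selected < 1:
        raise ValueError("need at least one selected window")
    return float(min(1.0, p_value * n_windows_tested / n_selected))
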