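"""Site-level QC filters applied to count tables before any inference.

The filters mirror standard Pool-seq practice on samtools-style pileup
summaries: masking around indels (±9 bp by default), removing sites with
three or more observed nucleotide classes, per-species read-depth bounds,
and bias p-value cuts (strand / tail-distance / base-quality) where that
annotation exists.

Three named coverage presets are provided because different analyses use
different depth bounds: ``scan`` (20–200×, the genome scan), ``sfs``
(80–200×, SFS estimation) and ``sitefst`` (40–200×, the per-site F_ST
summary).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np

from .io_formats import GenomeTable, logger


@dataclass(frozen=True)
class FilterConfig:
    indel_mask_radius: int = 9
    max_allele_classes: int = 2
    min_coverage: int = 20
    max_coverage: int = 200
    strand_bias_p: float = 1e-4
    tail_distance_p: float = 1e-4
    baseq_bias_p: float = 1e-100

    def __post_init__(self) -> None:
        if self.indel_mask_radius < 0:
            raise ValueError("indel_mask_radius must be >= 0")
        if not 0 < self.min_coverage <= self.max_coverage:
            raise ValueError("need 0 < min_coverage <= max_coverage")


PRESETS: Mapping[str, FilterConfig] = {
    "scan": FilterConfig(min_coverage=20, max_coverage=200),
    "sfs": FilterConfig(min_coverage=80, max_coverage=200),
    "sitefst": FilterConfig(min_coverage=40, max_coverage=200),
}


def preset(name: str, **overrides) -> FilterConfig:
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


def _near_indel_mask(pos: np.ndarray, indel_pos: np.ndarray,
                     radius: int) -> np.ndarray:
    """True for entries of sorted-or-not `pos` within `radius` of any indel
    position (both 1-based)."""
    if len(indel_pos) == 0:
        return np.zeros(len(pos), dtype=bool)
    indel_sorted = np.sort(np.asarray(indel_pos, dtype=np.int64))
    idx = np.searchsorted(indel_sorted, pos)
    near = np.zeros(len(pos), dtype=bool)
    right = idx < len(indel_sorted)
    near[right] = indel_sorted[idx[right]] - pos[right] <= radius
    left = idx > 0
    near[left] |= pos[left] - indel_sorted[idx[left] - 1] <= radius
    return near


def apply_site_filters(table: GenomeTable, cfg: FilterConfig,
                       indel_positions: Mapping[str, Iterable[int]]
                       | None = None) -> GenomeTable:
    """Return a new filtered table; the input is untouched.

    Removes, in order: sites within ``indel_mask_radius`` of an indel
    position (supplied per chromosome and/or flagged by the table's
    ``near_indel`` column — the union of both species' indels), sites with
    ``>= max_allele_classes + 1`` observed nucleotide classes, sites outside
    the coverage bounds in either species, and sites whose recorded bias
    p-values fall below the thresholds.  Filters whose annotation is absent
    are skipped (and logged once).
    """
    df = table.df
    keep = np.ones(len(df), dtype=bool)
    if len(df) == 0:
        return GenomeTable(df.copy(), table.n_pool, table.epsilon,
                           validate=False)

    chrom_arr = df["chrom"].to_numpy()
    pos_arr = df["pos"].to_numpy()
    indel_by_chrom: dict[str, list] = {}
    if indel_positions:
        for chrom, positions in indel_positions.items():
            indel_by_chrom.setdefault(chrom, []).extend(positions)
    if "near_indel" in df.columns:
        flagged = df.loc[df["near_indel"].astype(bool)]
        for chrom, sub in flagged.groupby("chrom", sort=False, observed=True):
            indel_by_chrom.setdefault(chrom, []).extend(
                sub["pos"].tolist())
    if indel_by_chrom:
        for chrom, positions in indel_by_chrom.items():
            sel = chrom_arr == chrom
            keep[sel] &= ~_near_indel_mask(pos_arr[sel],
                                           np.asarray(positions),
                                           cfg.indel_mask_radius)

    if "n_classes" in df.columns:
        keep &= df["n_classes"].to_numpy() <= cfg.max_allele_classes
    else:
        logger.debug("no n_classes column; allele-class filter skipped")

    for rc in ("r1", "r2"):
        r = df[rc].to_numpy()
        keep &= (r >= cfg.min_coverage) & (r <= cfg.max_coverage)

    for col, thr in (("p_strand", cfg.strand_bias_p),
                     ("p_tail", cfg.tail_distance_p),
                     ("p_baseq", cfg.baseq_bias_p)):
        if col in df.columns:
            p = df[col].to_numpy(dtype=float)
            keep &= ~(p < thr)  # NaN annotation -> keep
        else:
            logger.debug("no %s column; bias filter skipped", col)

    return GenomeTable(df.loc[keep].reset_index(drop=True),
                       table.n_pool, table.epsilon, validate=False)
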