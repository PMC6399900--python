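"""Reading and writing the pipeline's on-disk artifacts.

Coordinate conventions
----------------------
Input site tables use 1-based positions (pileup convention).  Every exported
interval file (DR calls, truth intervals) is 0-based half-open BED.  The
"focal" allele at a biallelic site is the globally minor allele summed over
both pools, ties broken by alphabetical nucleotide order, so that both
species' counts share one polarity and folded statistics are consistent.

Two tabular dialects are accepted:

``simple``
    ``chrom  pos  k1  r1  k2  r2`` — focal-allele read count and coverage
    per species.  This is the canonical internal format.
``sync``
    ``chrom  pos  ref  A:T:C:G:N:del  A:T:C:G:N:del`` — PoPoolation-style
    per-nucleotide count strings, one column per pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("poolscan")

_NUCS = ("A", "T", "C", "G")


@dataclass(frozen=True)
class SiteRecord:
    """One genomic site's pooled read counts for the two species."""

    chrom: str
    pos: int  # 1-based
    k1: int  # focal-allele reads, species 1
    r1: int  # coverage, species 1
    k2: int
    r2: int
    n_classes: int = 2  # distinct nucleotides observed across both pools
    near_indel: bool = False
    bias_pvals: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for k, r in ((self.k1, self.r1), (self.k2, self.r2)):
            if not 0 <= k <= r:
                raise ValueError(f"need 0 <= k <= r, got k={k}, r={r}")


#: optional columns a table may carry, with their dtypes
_OPTIONAL_COLS = {
    "n_classes": np.int8,
    "near_indel": bool,
    "p_strand": float,
    "p_tail": float,
    "p_baseq": float,
}
_CORE_COLS = ["chrom", "pos", "k1", "r1", "k2", "r2"]


class GenomeTable:
    """Ordered per-site count table for two pooled samples.

    Thin wrapper around a :class:`pandas.DataFrame` (columns ``chrom, pos,
    k1, r1, k2, r2`` plus optional QC columns) that enforces the site
    invariants: 0 ≤ k ≤ r, pos ≥ 1, strictly increasing positions within
    each chromosome.
    """

    def __init__(self, df: pd.DataFrame, n_pool: tuple[int, int] = (40, 40),
                 epsilon: float = 0.001, validate: bool = True):
        missing = [c for c in _CORE_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        self.n_pool = tuple(n_pool)
        self.epsilon = float(epsilon)
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if (df["pos"] < 1).any():
            raise ValueError("positions must be >= 1")
        for kc, rc in (("k1", "r1"), ("k2", "r2")):
            if (df[kc] < 0).any() or (df[kc] > df[rc]).any():
                raise ValueError(f"need 0 <= {kc} <= {rc}")
        for _, sub in df.groupby("chrom", sort=False, observed=True):
            d = np.diff(sub["pos"].to_numpy())
            if (d <= 0).any():
                raise ValueError("positions must be strictly increasing "
                                 "within each chromosome")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeTable):
            return NotImplemented
        a = self.df[_CORE_COLS].reset_index(drop=True)
        b = other.df[_CORE_COLS].reset_index(drop=True)
        return self.n_pool == other.n_pool and a.equals(b)

    def records(self) -> Iterator[SiteRecord]:
        has_nc = "n_classes" in self.df.columns
        has_ni = "near_indel" in self.df.columns
        for row in self.df.itertuples(index=False):
            yield SiteRecord(
                chrom=row.chrom, pos=int(row.pos),
                k1=int(row.k1), r1=int(row.r1),
                k2=int(row.k2), r2=int(row.r2),
                n_classes=int(row.n_classes) if has_nc else 2,
                near_indel=bool(row.near_indel) if has_ni else False,
            )


def _parse_sync_counts(token: str, path: str, lineno: int) -> np.ndarray:
    parts = token.split(":")
    if len(parts) != 6:
        raise ValueError(
            f"{path}:{lineno}: malformed count string {token!r} "
            "(expected A:T:C:G:N:del)")
    try:
        counts = np.array([int(p) for p in parts])
    except ValueError as exc:
        raise ValueError(
            f"{path}:{lineno}: non-integer count in {token!r}") from exc
    if (counts < 0).any():
        raise ValueError(f"{path}:{lineno}: negative count in {token!r}")
    return counts


def read_site_table(path: str | Path, dialect: str = "simple",
                    n_pool: tuple[int, int] = (40, 40),
                    epsilon: float = 0.001) -> GenomeTable:
    """Read a per-site count table.

    Unparseable lines raise ``ValueError`` carrying the 1-based line number.
    Lines starting with ``#`` are comments.
    """
    path = Path(path)
    if dialect not in ("simple", "sync"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if dialect == "simple":
                if len(fields) < 6:
                    raise ValueError(
                        f"{path}:{lineno}: expected >=6 columns, "
                        f"got {len(fields)}")
                chrom, pos = fields[0], fields[1]
                try:
                    rows.append((chrom, int(pos), *map(int, fields[2:6])))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer field") from exc
            else:
                if len(fields) < 5:
                    raise ValueError(
                        f"{path}:{lineno}: expected >=5 columns, "
                        f"got {len(fields)}")
                chrom, pos = fields[0], int(fields[1])
                c1 = _parse_sync_counts(fields[3], str(path), lineno)
                c2 = _parse_sync_counts(fields[4], str(path), lineno)
                nuc_tot = c1[:4] + c2[:4]
                observed = np.flatnonzero(nuc_tot > 0)
                n_classes = len(observed)
                # focal allele: global minor, ties broken alphabetically
                # (_NUCS order is the file's column order A,T,C,G; break ties
                # by nucleotide letter instead)
                if n_classes == 0:
                    focal = 0
                else:
                    order = sorted(observed,
                                   key=lambda i: (nuc_tot[i], _NUCS[i]))
                    focal = order[0] if n_classes > 1 else observed[0]
                    if n_classes == 1:
                        focal = -1  # monomorphic: focal count 0
                r1, r2 = int(c1[:4].sum()), int(c2[:4].sum())
                k1 = int(c1[focal]) if focal >= 0 else 0
                k2 = int(c2[focal]) if focal >= 0 else 0
                near_indel = bool(c1[5] > 0 or c2[5] > 0)
                rows.append((chrom, pos, k1, r1, k2, r2,
                             n_classes, near_indel))
    if dialect == "simple":
        df = pd.DataFrame(rows, columns=_CORE_COLS)
    else:
        df = pd.DataFrame(rows, columns=_CORE_COLS +
                          ["n_classes", "near_indel"])
    return GenomeTable(df, n_pool=n_pool, epsilon=epsilon)


def write_site_table(table: GenomeTable, path: str | Path) -> None:
    """Write a table in the simple dialect (round-trips with
    :func:`read_site_table`)."""
    table.df[_CORE_COLS].to_csv(path, sep="\t", header=False, index=False)


def write_window_stats(windows: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end", "n_sites", "pi_w", "pi_b", "fst"]
    windows[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_window_stats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sfs(phi: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tprobability\n")
        for c, p in enumerate(np.asarray(phi, dtype=float)):
            fh.write(f"{c}\t{p:.10g}\n")


def read_sfs(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df["probability"].to_numpy()


def write_null_distribution(values: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.sort(np.asarray(values, dtype=float)), fmt="%.8g")


def read_null_distribution(path: str | Path) -> np.ndarray:
    return np.atleast_1d(np.loadtxt(path))


def write_dr_bed(drs: Sequence, path: str | Path) -> None:
    """Write called differentiated regions as BED (0-based half-open).

    The score column is the DR's maximum window F_ST scaled by 1000 and
    clipped to [0, 1000].  Overlapping DRs on one chromosome are written
    as-is but flagged in the log.
    """
    drs = list(drs)
    by_chrom: dict[str, list] = {}
    for dr in drs:
        by_chrom.setdefault(dr.chrom, []).append(dr)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda d: d.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                logger.warning("overlapping DRs on %s: [%d,%d) and [%d,%d)",
                               chrom, a.start, a.end, b.start, b.end)
    with open(path, "w") as fh:
        fh.write("# poolscan differentiated regions "
                 "(chrom\tstart\tend\tname\tscore)\n")
        for i, dr in enumerate(sorted(drs, key=lambda d: (d.chrom, d.start))):
            if dr.end <= dr.start or dr.start < 0:
                raise ValueError(f"invalid DR interval [{dr.start},{dr.end})")
            score = int(np.clip(round(dr.max_fst * 1000), 0, 1000))
            name = getattr(dr, "name", None) or f"DR{i + 1}"
            fh.write(f"{dr.chrom}\t{dr.start}\t{dr.end}\t{name}\t{score}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]),
                         f[3] if len(f) > 3 else "",
                         int(f[4]) if len(f) > 4 else 0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "name", "score"])
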