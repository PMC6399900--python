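"""Synthetic two-species Pool-seq genomes with known truth.

Emulates the study conditions of a very recently diverged species pair
sequenced as pools: an expansion-shaped folded SFS with a strong singleton
excess, near-zero genome-wide differentiation (high effective migration,
background 4Nm = 50 so E[F_ST] ≈ 1/(1+8Nm) ≈ 0.0099), ~34× mean Poisson
coverage of n = 40 chromosomes per species with sequencing error ε, and 21
planted differentiated regions (DRs) of 14–28 kb each containing 1–7 fixed
differences.

The genome is deliberately desk-scale: default 24 chromosomes × 20 Mb with
a scaled-down per-bp mutation rate (so segregating-site density is a few
per kb rather than the tens per kb of a real cichlid genome), and
monomorphic "anchor" sites on a 500-bp grid that carry the per-window
coverage bookkeeping the scan's >=50%-covered rule needs.  Inside each
planted DR the species' allele frequencies follow a divergent-selection
profile taken from the two-locus simulator (new-mutation mode, 4Ns = 400,
4Nm = 50, T = 0.5N), mapped onto physical distance with a fixed
4Nr-per-bp scale chosen so the neutral end of the profile (4Nr = 200) is
reached a quarter of the DR length from the DR centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .coalescent_null import DemographyModel, EXPANSION, _biallelic_matrix
from .divsel_sim import (DivSelParams, neutral_equilibrium_stats,
                         run_divergent_selection)
from .io_formats import GenomeTable, read_bed

__all__ = ["SyntheticConfig", "TruthSet", "generate_two_species_dataset",
           "emit_truth_bed", "read_truth"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_chroms: int = 24
    chrom_length: int = 20_000_000
    n_pool: int = 40
    mean_coverage: float = 34.0
    epsilon: float = 0.001
    fourNm: float = 50.0
    demography: DemographyModel = EXPANSION
    mu: float = 3e-9           # per bp per generation (scaled-down density)
    recomb_rate: float = 2.5e-9  # per bp per generation (short genealogy blocks)
    anchor_spacing: int = 500
    n_drs: int = 21
    dr_length_range: tuple[int, int] = (14_000, 28_000)
    fixed_diffs_range: tuple[int, int] = (1, 7)
    dr_edge_margin: int = 200_000
    dr_separation: int = 200_000
    profile_reps: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.dr_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid dr_length_range")
        need = (self.n_drs * (hi + self.dr_separation)
                + 2 * self.dr_edge_margin)
        if need > self.n_chroms * self.chrom_length:
            raise ValueError("genome too small for the requested DRs")


@dataclass
class TruthSet:
    """Planted truth: DR intervals (0-based half-open), fixed-difference
    positions (1-based) and true pool frequencies at modified sites."""

    drs: pd.DataFrame            # chrom, start, end, n_fixed, direction
    fixed_diffs: pd.DataFrame    # chrom, pos
    site_freqs: pd.DataFrame | None = None  # chrom, pos, p1, p2 (DR sites)

    def validate(self) -> None:
        for _, fd in self.fixed_diffs.iterrows():
            hit = self.drs[(self.drs["chrom"] == fd["chrom"])
                           & (self.drs["start"] < fd["pos"])
                           & (fd["pos"] <= self.drs["end"])]
            if len(hit) == 0:
                raise ValueError(
                    f"fixed difference {fd['chrom']}:{fd['pos']} outside "
                    "every planted DR")


def _two_deme_demography(cfg: SyntheticConfig) -> msprime.Demography:
    """Two-island model with 4N(t)·m(t) held constant through the
    expansion, so the scaled process (and hence E[F_ST]) matches the
    constant-size island model."""
    d = cfg.demography
    demog = msprime.Demography()
    demog.add_population(name="sp1", initial_size=d.N_current)
    demog.add_population(name="sp2", initial_size=d.N_current)
    m_cur = cfg.fourNm / (4.0 * d.N_current)
    demog.set_symmetric_migration_rate(["sp1", "sp2"], m_cur)
    if d.mode == "expansion":
        demog.add_population_parameters_change(
            time=d.t_expansion, initial_size=d.N_ancestral)
        m_anc = cfg.fourNm / (4.0 * d.N_ancestral)
        demog.add_migration_rate_change(time=d.t_expansion, rate=m_anc)
    return demog


def _divsel_profile(cfg: SyntheticConfig, seed: int):
    """(log10-4Nr grid, differentiated-fraction F, relative heterozygosity
    h) from the two-locus simulator at T = 0.5N."""
    params = DivSelParams.from_scaled(
        fourNm=cfg.fourNm, fourNs=400.0, N=1000,
        reps=cfg.profile_reps, init_mode="new_mutation")
    grid = np.array([0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0,
                     100.0, 200.0])
    traj = run_divergent_selection(params, fourNr_grid=grid,
                                   time_points=[500], seed=seed)
    neutral = neutral_equilibrium_stats(params, reps=min(cfg.profile_reps,
                                                         500),
                                        seed=seed + 1)
    fst_n = max(neutral["fst"], 0.0)
    fst = traj.fst[:, 0]
    F = np.clip((fst - fst_n) / max(1.0 - fst_n, 1e-9), 0.0, 1.0)
    pw = traj.pi_w()[:, 0]
    h = np.clip(pw / max(neutral["pi_w1"], 1e-12), 0.0, 1.0)
    return np.log10(grid), F, h


def _place_drs(cfg: SyntheticConfig, rng: np.random.Generator
               ) -> pd.DataFrame:
    """Random non-overlapping DR intervals with edge margins."""
    rows = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    lo, hi = cfg.dr_length_range
    attempts = 0
    while len(rows) < cfg.n_drs:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("DR placement failed after bounded retries")
        c = int(rng.integers(cfg.n_chroms))
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(cfg.dr_edge_margin,
                                 cfg.chrom_length - cfg.dr_edge_margin
                                 - length))
        end = start + length
        clash = any(start - cfg.dr_separation < e
                    and s < end + cfg.dr_separation
                    for s, e in occupied.get(c, []))
        if clash:
            continue
        occupied.setdefault(c, []).append((start, end))
        n_fd = int(rng.integers(cfg.fixed_diffs_range[0],
                                cfg.fixed_diffs_range[1] + 1))
        direction = int(rng.integers(2))  # which species carries the
        rows.append((f"chr{c + 1}", start, end, n_fd, direction))
    rows.sort(key=lambda r: (int(r[0][3:]), r[1]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "n_fixed", "direction"])


def generate_two_species_dataset(cfg: SyntheticConfig
                                 ) -> tuple[GenomeTable, TruthSet]:
    """Generate the full two-species Pool-seq site table plus its truth.

    Background sites come from a two-deme structured coalescent (40
    chromosomes sampled per deme — the pools themselves); planted DR sites
    overwrite the background with the divergent-selection frequency
    profile; Pool-seq read counts are then drawn for every site
    (``r ~ Poisson(mean_coverage)``, ``k ~ Binom(r, (1−ε)a/n + ε(1−a/n))``).
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pool
    drs = _place_drs(cfg, rng)
    logg, F_prof, h_prof = _divsel_profile(cfg, seed=int(rng.integers(2**31)))
    demog = _two_deme_demography(cfg)
    mut_model = msprime.BinaryMutationModel()

    frames = []
    fixed_rows = []
    freq_rows = []
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        s1, s2 = rng.integers(1, 2**31, size=2)
        ts = msprime.sim_ancestry(
            samples={"sp1": n // 2, "sp2": n // 2}, ploidy=2,
            sequence_length=cfg.chrom_length,
            recombination_rate=cfg.recomb_rate, demography=demog,
            random_seed=int(s1))
        ts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=int(s2),
                                   model=mut_model)
        pos_f, gm = _biallelic_matrix(ts)
        pos = pos_f.astype(np.int64) + 1  # 1-based
        # discrete-genome collisions: keep first at each position
        uniq = np.concatenate([[True], np.diff(pos) > 0])
        pos, gm = pos[uniq], gm[uniq]
        a1 = gm[:, :n].sum(axis=1).astype(np.int64)
        a2 = gm[:, n:].sum(axis=1).astype(np.int64)

        # anchors on a grid, skipping collisions with segregating sites
        anchors = np.arange(cfg.anchor_spacing, cfg.chrom_length + 1,
                            cfg.anchor_spacing, dtype=np.int64)
        anchors = anchors[~np.isin(anchors, pos)]
        all_pos = np.concatenate([pos, anchors])
        all_a1 = np.concatenate([a1, np.zeros(len(anchors), np.int64)])
        all_a2 = np.concatenate([a2, np.zeros(len(anchors), np.int64)])
        order = np.argsort(all_pos, kind="stable")
        all_pos, all_a1, all_a2 = (all_pos[order], all_a1[order],
                                   all_a2[order])

        # plant DRs
        for dr in drs[drs["chrom"] == chrom].itertuples(index=False):
            center = (dr.start + dr.end) / 2.0
            quarter = (dr.end - dr.start) / 4.0
            scale = 200.0 / quarter  # 4Nr units per bp
            inside = np.flatnonzero((all_pos - 1 >= dr.start)
                                    & (all_pos - 1 < dr.end)
                                    & ((all_a1 > 0) | (all_a2 > 0)))
            d_bp = np.abs(all_pos[inside] - 1 - center)
            g = np.clip(d_bp * scale, 10**logg[0], 10**logg[-1])
            F = np.interp(np.log10(g), logg, F_prof)
            h = np.interp(np.log10(g), logg, h_prof)
            u = rng.random(len(inside))
            v = rng.random(len(inside))
            diff = u < F
            mono = (~diff) & (v > h)
            p_hi = rng.uniform(0.9, 1.0, size=len(inside))
            p_lo = rng.uniform(0.0, 0.1, size=len(inside))
            pa = np.where(dr.direction == 0, p_hi, p_lo)
            pb = np.where(dr.direction == 0, p_lo, p_hi)
            sel = inside[diff]
            all_a1[sel] = rng.binomial(n, pa[diff])
            all_a2[sel] = rng.binomial(n, pb[diff])
            all_a1[inside[mono]] = 0
            all_a2[inside[mono]] = 0
            for i, p1v, p2v in zip(sel, pa[diff], pb[diff]):
                freq_rows.append((chrom, int(all_pos[i]),
                                  float(p1v), float(p2v)))

            # planted fixed differences near the DR centre
            lo_p = int(center - 0.15 * (dr.end - dr.start)) + 1
            hi_p = int(center + 0.15 * (dr.end - dr.start))
            candidates = np.setdiff1d(
                rng.integers(lo_p, hi_p + 1, size=50 * dr.n_fixed),
                all_pos)
            if len(candidates) < dr.n_fixed:
                raise RuntimeError("DR fixed-difference placement failed")
            fd_pos = np.sort(rng.choice(candidates, size=dr.n_fixed,
                                        replace=False))
            fd_a1 = np.full(dr.n_fixed, n if dr.direction == 0 else 0,
                            dtype=np.int64)
            fd_a2 = n - fd_a1
            ins = np.searchsorted(all_pos, fd_pos)
            all_pos = np.insert(all_pos, ins, fd_pos)
            all_a1 = np.insert(all_a1, ins, fd_a1)
            all_a2 = np.insert(all_a2, ins, fd_a2)
            for pfd in fd_pos:
                fixed_rows.append((chrom, int(pfd)))
                freq_rows.append((chrom, int(pfd),
                                  1.0 if dr.direction == 0 else 0.0,
                                  0.0 if dr.direction == 0 else 1.0))

        # Pool-seq reads
        S = len(all_pos)
        r1 = rng.poisson(cfg.mean_coverage, size=S)
        r2 = rng.poisson(cfg.mean_coverage, size=S)
        e = cfg.epsilon
        pr1 = (1 - e) * all_a1 / n + e * (1 - all_a1 / n)
        pr2 = (1 - e) * all_a2 / n + e * (1 - all_a2 / n)
        k1 = rng.binomial(r1, pr1)
        k2 = rng.binomial(r2, pr2)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": all_pos,
            "k1": k1.astype(np.int32), "r1": r1.astype(np.int32),
            "k2": k2.astype(np.int32), "r2": r2.astype(np.int32),
            # truth channel: the pools' true allele counts (not written to
            # disk by write_site_table; used for validation)
            "a1": all_a1.astype(np.int16), "a2": all_a2.astype(np.int16),
        }))

    df = pd.concat(frames, ignore_index=True)
    table = GenomeTable(df, n_pool=(n, n), epsilon=cfg.epsilon,
                        validate=False)
    truth = TruthSet(
        drs=drs,
        fixed_diffs=pd.DataFrame(fixed_rows, columns=["chrom", "pos"]),
        site_freqs=pd.DataFrame(freq_rows,
                                columns=["chrom", "pos", "p1", "p2"]),
    )
    truth.validate()
    return table, truth


def emit_truth_bed(truth: TruthSet, bed_path: str | Path,
                   fixed_path: str | Path | None = None) -> None:
    """Write planted DRs as BED plus a companion fixed-difference TSV."""
    truth.validate()
    bed_path = Path(bed_path)
    if fixed_path is None:
        fixed_path = bed_path.with_suffix(".fixed.tsv")
    with open(bed_path, "w") as fh:
        fh.write("# poolscan planted differentiated regions\n")
        for i, dr in enumerate(truth.drs.itertuples(index=False)):
            fh.write(f"{dr.chrom}\t{dr.start}\t{dr.end}\t"
                     f"TRUTH{i + 1}\t{dr.n_fixed}\n")
    truth.fixed_diffs.to_csv(fixed_path, sep="\t", index=False)


def read_truth(bed_path: str | Path,
               fixed_path: str | Path | None = None) -> TruthSet:
    bed_path = Path(bed_path)
    if fixed_path is None:
        fixed_path = bed_path.with_suffix(".fixed.tsv")
    bed = read_bed(bed_path)
    drs = bed.rename(columns={"score": "n_fixed"})[
        ["chrom", "start", "end", "n_fixed"]].copy()
    drs["direction"] = 0
    fixed = pd.read_csv(fixed_path, sep="\t")
    return TruthSet(drs=drs, fixed_diffs=fixed)
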