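"""Coalescent + Pool-seq resampling null models.

Simulates the panmixia null used for the neutrality test and the
coverage-binned F_ST summary: a coalescent sample of 80 chromosomes (under
a population-expansion demography) is randomly split into two
pseudo-populations of 40, Pool-seq reads are drawn from each with
sequencing error, allele frequencies are re-estimated and F_ST computed —
so the null carries the full estimation noise of the observed data.
Also provides a two-deme structured model for power analysis, with the
migration rate tuned so that the expected differentiation matches a target
via F_ST = 1/(1 + 8Nm).

The coalescent engine is msprime behind this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from .genome_scan import fst_value, site_pi_between, site_pi_within
from .poolseq_inference import (FoldedSFS, PoolModel, estimate_sfs_em,
                                ml_frequency_lookup,
                                posterior_frequency_lookup)

__all__ = ["DemographyModel", "HaplotypeSample", "simulate_panmictic_sample",
           "split_panmictic", "poolseq_reads_from_pool",
           "null_fst_distribution", "detection_power",
           "panmixia_sitewise_fst", "simulate_two_deme_counts"]


@dataclass(frozen=True)
class DemographyModel:
    """Single-population demography for the null simulations.

    ``expansion`` mode: size ``N_ancestral`` until ``t_expansion``
    generations ago, then ``N_current`` (instantaneous) or exponential
    growth towards the present.  Sizes are diploid effective sizes.
    """

    mode: str = "expansion"
    N_current: float = 1e6
    N_ancestral: float = 2e4
    t_expansion: float = 7500.0
    growth: str = "instantaneous"

    def __post_init__(self) -> None:
        if self.N_current <= 0 or self.N_ancestral <= 0:
            raise ValueError("population sizes must be > 0")
        if self.t_expansion < 0:
            raise ValueError("t_expansion must be >= 0")
        if self.mode not in ("constant", "expansion"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.growth not in ("instantaneous", "exponential"):
            raise ValueError(f"unknown growth {self.growth!r}")

    def to_msprime(self) -> msprime.Demography:
        demog = msprime.Demography()
        if self.mode == "constant":
            demog.add_population(name="pop0",
                                 initial_size=self.N_current)
            return demog
        if self.growth == "exponential":
            rate = np.log(self.N_current / self.N_ancestral) \
                / self.t_expansion
            demog.add_population(name="pop0", initial_size=self.N_current,
                                 growth_rate=rate)
            demog.add_population_parameters_change(
                time=self.t_expansion, initial_size=self.N_ancestral,
                growth_rate=0.0, population="pop0")
        else:
            demog.add_population(name="pop0", initial_size=self.N_current)
            demog.add_population_parameters_change(
                time=self.t_expansion, initial_size=self.N_ancestral,
                population="pop0")
        return demog


CONSTANT = DemographyModel(mode="constant")
EXPANSION = DemographyModel(mode="expansion")


@dataclass
class HaplotypeSample:
    """Segregating sites of a haploid sample: positions in [0, L) and a
    sites × chromosomes 0/1 matrix."""

    n_chromosomes: int
    length: float
    positions: np.ndarray
    genotypes: np.ndarray  # shape (S, n_chromosomes), int8

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.positions),
                                    self.n_chromosomes):
            raise ValueError("genotype matrix shape mismatch")

    @property
    def num_sites(self) -> int:
        return len(self.positions)

    def allele_counts(self) -> np.ndarray:
        return self.genotypes.sum(axis=1)


def _biallelic_matrix(ts) -> tuple[np.ndarray, np.ndarray]:
    """Positions and 0/1 genotypes of sites segregating in the sample."""
    if ts.num_sites == 0:
        n = ts.num_samples
        return np.empty(0), np.empty((0, n), dtype=np.int8)
    gm = ts.genotype_matrix()
    # keep strictly biallelic segregating sites (finite-sites collisions
    # can create >2 alleles; drop them)
    counts = gm.sum(axis=1)
    ok = (gm.max(axis=1) == 1) & (counts > 0) & (counts < ts.num_samples)
    pos = ts.sites_position[ok]
    return pos, gm[ok].astype(np.int8)


def simulate_panmictic_sample(n: int = 80, L: float = 10_000.0,
                              theta: float = 0.004,
                              demography: DemographyModel = EXPANSION,
                              rho: float = 0.0,
                              seed: int | None = None) -> HaplotypeSample:
    """One panmictic coalescent replicate with infinite-sites-style
    mutation.

    ``theta`` is the per-bp population-scaled mutation rate 4·N_current·μ
    (so the per-generation rate handed to the engine is
    θ/(4·N_current)); ``rho`` is defined analogously for recombination and
    defaults to 0 to match the no-recombination null.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    mu = theta / (4.0 * demography.N_current)
    r = rho / (4.0 * demography.N_current)
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(1, 2**31, size=2)
    ts = msprime.sim_ancestry(
        samples={"pop0": n // 2}, ploidy=2, sequence_length=L,
        recombination_rate=r, demography=demography.to_msprime(),
        random_seed=int(s1))
    ts = msprime.sim_mutations(ts, rate=mu, random_seed=int(s2),
                               model=msprime.BinaryMutationModel())
    pos, gm = _biallelic_matrix(ts)
    return HaplotypeSample(n_chromosomes=n, length=L, positions=pos,
                           genotypes=gm)


def split_panmictic(sample: HaplotypeSample, sizes: tuple[int, int] = (40, 40),
                    seed: int | None = None
                    ) -> tuple[HaplotypeSample, HaplotypeSample]:
    """Uniform random partition of the chromosomes into two subsamples."""
    if sum(sizes) != sample.n_chromosomes:
        raise ValueError("sizes must sum to the number of chromosomes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sample.n_chromosomes)
    a, b = perm[:sizes[0]], perm[sizes[0]:]
    return (HaplotypeSample(sizes[0], sample.length, sample.positions,
                            sample.genotypes[:, a]),
            HaplotypeSample(sizes[1], sample.length, sample.positions,
                            sample.genotypes[:, b]))


def poolseq_reads_from_pool(sample: HaplotypeSample,
                            coverage_model, epsilon: float = 0.001,
                            seed: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate pooled reads: each read picks a chromosome uniformly with
    replacement and reports its allele, flipped with probability ε.

    Implemented as the exactly equivalent draw
    k ~ Binomial(r, (1−ε)·a/n + ε·(1−a/n)) at a site with a focal copies
    among n chromosomes.  ``coverage_model`` is either a fixed integer depth
    or ``("poisson", λ)``.  Returns (k, r) arrays over the sample's sites.
    """
    rng = np.random.default_rng(seed)
    S = sample.num_sites
    if isinstance(coverage_model, (int, np.integer)):
        r = np.full(S, int(coverage_model))
    else:
        kind, lam = coverage_model
        if kind != "poisson":
            raise ValueError(f"unknown coverage model {kind!r}")
        r = rng.poisson(lam, size=S)
    a = sample.allele_counts()
    p = (1.0 - epsilon) * a / sample.n_chromosomes \
        + epsilon * (1.0 - a / sample.n_chromosomes)
    k = rng.binomial(r, p)
    return k, r


def _window_fst_from_counts(k1, r1, k2, r2, freq_lut, n) -> float:
    """Window F_ST (ratio of summed π's) from read counts via a frequency
    lookup table ``freq_lut[r, k]``."""
    p1 = freq_lut[r1, k1]
    p2 = freq_lut[r2, k2]
    pw = 0.5 * (site_pi_within(p1, n) + site_pi_within(p2, n))
    pb = site_pi_between(p1, p2)
    return fst_value(np.sum(pw), np.sum(pb))


def _calibration_prior(counts_iter, model: PoolModel) -> FoldedSFS:
    """Folded-SFS prior EM-estimated from simulated calibration counts —
    mirrors estimating the SFS from the observed data before per-site
    frequency estimation."""
    ks, rs = [], []
    for k, r in counts_iter:
        ks.append(np.asarray(k))
        rs.append(np.asarray(r))
    recs = np.column_stack([np.concatenate(ks), np.concatenate(rs)])
    return estimate_sfs_em(recs, model)


def null_fst_distribution(reps: int = 100_000, coverage: int = 20,
                          window: float = 10_000.0, theta: float = 0.004,
                          demography: DemographyModel = EXPANSION,
                          seed: int | None = None, n: int = 80,
                          sizes: tuple[int, int] = (40, 40),
                          epsilon: float = 0.001) -> np.ndarray:
    """Null window-F_ST distribution under panmixia.

    Per replicate: simulate one non-recombining window of 80 chromosomes,
    split randomly 40/40, draw pooled reads at fixed ``coverage`` for both
    species, re-estimate allele frequencies by ML and compute the window
    F_ST.  Returns the sorted empirical distribution (replicates whose
    F_ST is undefined — no estimated polymorphism — are dropped).
    """
    rng = np.random.default_rng(seed)
    mu = theta / (4.0 * demography.N_current)
    model = PoolModel(n=sizes[0], epsilon=epsilon)
    anc_seed, mut_seed = rng.integers(1, 2**31, size=2)
    reps_ts = msprime.sim_ancestry(
        samples={"pop0": n // 2}, ploidy=2, sequence_length=window,
        demography=demography.to_msprime(), num_replicates=reps,
        random_seed=int(anc_seed))
    counts: list[tuple[np.ndarray, np.ndarray]] = []
    for i, ts in enumerate(reps_ts):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(mut_seed + i),
            model=msprime.BinaryMutationModel())
        _, gm = _biallelic_matrix(mts)
        if gm.shape[0] == 0:
            counts.append((np.empty(0, np.int64), np.empty(0, np.int64)))
            continue
        perm = rng.permutation(n)
        a1 = gm[:, perm[:sizes[0]]].sum(axis=1)
        a2 = gm[:, perm[sizes[0]:]].sum(axis=1)
        p1r = (1 - epsilon) * a1 / sizes[0] + epsilon * (1 - a1 / sizes[0])
        p2r = (1 - epsilon) * a2 / sizes[1] + epsilon * (1 - a2 / sizes[1])
        counts.append((rng.binomial(coverage, p1r),
                       rng.binomial(coverage, p2r)))
    # prior: folded SFS estimated from the simulated reads themselves
    prior = _calibration_prior(
        (((np.concatenate([k1, k2])),
          np.full(len(k1) + len(k2), coverage))
         for k1, k2 in counts if len(k1)), model)
    lut = posterior_frequency_lookup(coverage, model, prior)
    out = np.empty(reps)
    for i, (k1, k2) in enumerate(counts):
        if len(k1) == 0:
            out[i] = np.nan
            continue
        r_arr = np.full(len(k1), coverage)
        out[i] = _window_fst_from_counts(k1, r_arr, k2, r_arr, lut, model.n)
    return np.sort(out[~np.isnan(out)])


def simulate_two_deme_counts(target_fst: float, n_per_pop: int = 40,
                             L: float = 10_000.0, theta: float = 0.004,
                             N: float = 1e5, num_replicates: int = 1,
                             seed: int | None = None):
    """Yield (a1, a2, S) allele-count pairs from a symmetric two-deme
    island model whose migration rate is tuned to the target F_ST.

    Uses F_ST = 1/(1 + 8Nm): the scaled rate 4Nm = (1/F − 1)/2.  A target
    of 0 means panmixia (simulated as one population randomly split).
    """
    if not 0 <= target_fst < 1:
        raise ValueError("target F_ST must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mu = theta / (4.0 * N)
    anc_seed, mut_seed = rng.integers(1, 2**31, size=2)
    if target_fst == 0:
        demog = msprime.Demography()
        demog.add_population(name="pop0", initial_size=N)
        samples = {"pop0": n_per_pop}
    else:
        fourNm = (1.0 / target_fst - 1.0) / 2.0
        m = fourNm / (4.0 * N)
        demog = msprime.Demography()
        demog.add_population(name="pop0", initial_size=N)
        demog.add_population(name="pop1", initial_size=N)
        demog.set_symmetric_migration_rate(["pop0", "pop1"], m)
        samples = {"pop0": n_per_pop // 2, "pop1": n_per_pop // 2}
    reps_ts = msprime.sim_ancestry(
        samples=samples, ploidy=2, sequence_length=L, demography=demog,
        num_replicates=num_replicates, random_seed=int(anc_seed))
    for i, ts in enumerate(reps_ts):
        mts = msprime.sim_mutations(
            ts, rate=mu, random_seed=int(mut_seed + i),
            model=msprime.BinaryMutationModel())
        _, gm = _biallelic_matrix(mts)
        if target_fst == 0:
            perm = rng.permutation(2 * n_per_pop)
            a1 = gm[:, perm[:n_per_pop]].sum(axis=1)
            a2 = gm[:, perm[n_per_pop:]].sum(axis=1)
        else:
            a1 = gm[:, :n_per_pop].sum(axis=1)
            a2 = gm[:, n_per_pop:].sum(axis=1)
        yield a1, a2


def _genome_avg_fst(counts_iter, n_per_pop, coverage, epsilon, freq_lut,
                    rng):
    vals = []
    for a1, a2 in counts_iter:
        if len(a1) == 0:
            continue
        p1r = (1 - epsilon) * a1 / n_per_pop + epsilon * (1 - a1 / n_per_pop)
        p2r = (1 - epsilon) * a2 / n_per_pop + epsilon * (1 - a2 / n_per_pop)
        k1 = rng.binomial(coverage, p1r)
        k2 = rng.binomial(coverage, p2r)
        r_arr = np.full(len(k1), coverage)
        vals.append(_window_fst_from_counts(k1, r_arr, k2, r_arr, freq_lut,
                                            n_per_pop))
    vals = np.asarray(vals, dtype=float)
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if len(vals) else np.nan


def detection_power(true_fst_target: float, n_per_pop: int = 40,
                    coverage: int = 34, n_regions: int = 30,
                    reps: int = 200, null_reps: int = 400,
                    alpha: float = 0.05, theta: float = 0.004,
                    N: float = 1e5, seed: int | None = None) -> float:
    """Power to detect genome-wide differentiation at a target F_ST.

    Each replicate genome is ``n_regions`` independent 10-kb windows of a
    two-deme island model tuned to the target; the test statistic is the
    genome-average window F_ST (after Pool-seq read noise and
    posterior-mean frequency re-estimation), compared against the (1−α)
    quantile of the same statistic under panmixia.
    """
    if true_fst_target >= 1:
        raise ValueError("target must be < 1")
    rng = np.random.default_rng(seed)
    model = PoolModel(n=n_per_pop, epsilon=0.001)

    # shrinkage prior from a panmictic calibration batch
    s_cal, s_null, s_alt = (int(v) for v in rng.integers(1, 2**30, size=3))
    cal = simulate_two_deme_counts(0.0, n_per_pop=n_per_pop, theta=theta,
                                   N=N, num_replicates=50, seed=s_cal)
    cal_counts = []
    for a1, a2 in cal:
        for a in (a1, a2):
            pr = (1 - model.epsilon) * a / n_per_pop \
                + model.epsilon * (1 - a / n_per_pop)
            cal_counts.append((rng.binomial(coverage, pr),
                               np.full(len(a), coverage)))
    prior = _calibration_prior(cal_counts, model)
    freq_lut = posterior_frequency_lookup(coverage, model, prior)

    def batch(target, nrep, sd):
        stats = np.empty(nrep)
        for j in range(nrep):
            it = simulate_two_deme_counts(
                target, n_per_pop=n_per_pop, theta=theta, N=N,
                num_replicates=n_regions, seed=int(sd + j))
            stats[j] = _genome_avg_fst(it, n_per_pop, coverage,
                                       model.epsilon, freq_lut, rng)
        return stats[~np.isnan(stats)]

    null_stats = batch(0.0, null_reps, s_null)
    crit = np.quantile(null_stats, 1.0 - alpha)
    alt_stats = batch(true_fst_target, reps, s_alt)
    return float(np.mean(alt_stats > crit))


def panmixia_sitewise_fst(min_sites: int = 100_000,
                          coverage_range: tuple[int, int] = (20, 50),
                          epsilon: float = 0.001, theta: float = 0.004,
                          demography: DemographyModel = EXPANSION,
                          window: float = 10_000.0, n: int = 80,
                          sizes: tuple[int, int] = (40, 40),
                          seed: int | None = None):
    """Per-site F_ST and coverages for >= min_sites segregating sites
    simulated under panmixia (the coverage-binned F_ST summary's input).

    Coverage is drawn uniformly over ``coverage_range`` (inclusive) per
    site and species.  Frequencies are posterior means under the folded
    SFS estimated by EM from the simulated reads themselves, mirroring the
    estimation applied to observed data.  Returns (fst, cov1, cov2)
    arrays; sites whose estimated π_B is 0 have NaN F_ST and are excluded
    downstream by :func:`poolscan.genome_scan.fst_by_coverage_bins`.
    """
    rng = np.random.default_rng(seed)
    mu = theta / (4.0 * demography.N_current)
    model = PoolModel(n=sizes[0], epsilon=epsilon)
    lo, hi = coverage_range
    anc_seed, mut_seed = rng.integers(1, 2**31, size=2)
    # pass 1: simulate read counts until enough segregating sites
    k1_parts, k2_parts, r1_parts, r2_parts = [], [], [], []
    total = 0
    batch_reps = max(1, int(min_sites // max(1.0, theta / 2 * window) // 8))
    batch_no = 0
    rep_counter = 0
    while total < min_sites:
        reps_ts = msprime.sim_ancestry(
            samples={"pop0": n // 2}, ploidy=2, sequence_length=window,
            demography=demography.to_msprime(), num_replicates=batch_reps,
            random_seed=int(anc_seed + batch_no))
        for ts in reps_ts:
            rep_counter += 1
            mts = msprime.sim_mutations(
                ts, rate=mu, random_seed=int(mut_seed + rep_counter),
                model=msprime.BinaryMutationModel())
            _, gm = _biallelic_matrix(mts)
            if gm.shape[0] == 0:
                continue
            perm = rng.permutation(n)
            a1 = gm[:, perm[:sizes[0]]].sum(axis=1)
            a2 = gm[:, perm[sizes[0]:]].sum(axis=1)
            S = len(a1)
            r1 = rng.integers(lo, hi + 1, size=S)
            r2 = rng.integers(lo, hi + 1, size=S)
            pr1 = (1 - epsilon) * a1 / sizes[0] \
                + epsilon * (1 - a1 / sizes[0])
            pr2 = (1 - epsilon) * a2 / sizes[1] \
                + epsilon * (1 - a2 / sizes[1])
            k1_parts.append(rng.binomial(r1, pr1))
            k2_parts.append(rng.binomial(r2, pr2))
            r1_parts.append(r1)
            r2_parts.append(r2)
            total += S
        batch_no += 1
    k1 = np.concatenate(k1_parts)
    k2 = np.concatenate(k2_parts)
    r1 = np.concatenate(r1_parts)
    r2 = np.concatenate(r2_parts)
    # pass 2: EM prior from the reads, then posterior-mean frequencies
    prior = _calibration_prior([(np.concatenate([k1, k2]),
                                 np.concatenate([r1, r2]))], model)
    lut = posterior_frequency_lookup(hi, model, prior)
    p1 = lut[r1, k1]
    p2 = lut[r2, k2]
    pw = 0.5 * (site_pi_within(p1, model.n) + site_pi_within(p2, model.n))
    pb = site_pi_between(p1, p2)
    return fst_value(pw, pb), r1, r2
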