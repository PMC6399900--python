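"""Two-locus, two-population migration–selection–drift simulator.

The model: an isolation-with-migration pair of populations of size N each.
Locus I carries alleles A/a and is the target of divergent selection —
A is favoured in population 1 and a in population 2, both with additive
selection coefficient s.  Locus II is neutral with alleles B/b, symmetric
mutation at rate μ per generation, and recombines with locus I at rate r.
Migration is symmetric at rate m per gamete per generation.  Haplotype
frequencies (A-B, A-b, a-B, a-b) are (x1..x4) in population 1 and (y1..y4)
in population 2; with D_x = x1·x4 − x2·x3 (D_y analogous) the expected
next-generation frequencies are

    x1' = (1−μ)x1 + μx2 − rD_x − m(x1−y1) + s·x1(x3+x4)
    x2' = (1−μ)x2 + μx1 + rD_x − m(x2−y2) + s·x2(x3+x4)
    x3' = (1−μ)x3 + μx4 + rD_x − m(x3−y3) − s·x3(x1+x2)
    x4' = (1−μ)x4 + μx3 − rD_x − m(x4−y4) − s·x4(x1+x2)

and the mirror images (selection signs swapped) for y.  The deterministic
update conserves the frequency simplex exactly.  Drift is per-population
multinomial resampling of 2N gametes around the deterministic expectation.

When selection is much stronger than migration the beneficial alleles
settle at the deterministic migration–selection equilibrium

    p̂ = −m/s + 1/2 + sqrt((m/s)² + 1/4),

which is also the exact symmetric fixed point of the recursion with
μ = r = 0.  Trajectories of heterozygosity at locus II (π_W per population,
π_B between, F_ST) as a function of the scaled distance 4Nr from the
selected site show the transient sweep-like trough and its subsequent
shrinkage to a short differentiated region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TwoLocusState", "DivSelParams", "TrajectoryGrid",
           "equilibrium_frequency", "deterministic_step",
           "stochastic_generation", "run_divergent_selection",
           "neutral_equilibrium_stats", "summarize_locus_stats"]


@dataclass
class TwoLocusState:
    """Haplotype frequencies (A-B, A-b, a-B, a-b) in the two populations."""

    x: np.ndarray  # shape (..., 4)
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        for arr, name in ((self.x, "x"), (self.y, "y")):
            if arr.shape[-1] != 4:
                raise ValueError(f"{name} must have 4 haplotype entries")
            if (arr < -1e-12).any() or (arr > 1 + 1e-12).any():
                raise ValueError(f"{name} frequencies outside [0, 1]")
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"{name} frequencies must sum to 1")

    @property
    def D_x(self):
        return self.x[..., 0] * self.x[..., 3] - self.x[..., 1] * self.x[..., 2]

    @property
    def D_y(self):
        return self.y[..., 0] * self.y[..., 3] - self.y[..., 1] * self.y[..., 2]

    def freq_A(self):
        """Frequency of the selected A allele (pop1, pop2)."""
        return self.x[..., :2].sum(axis=-1), self.y[..., :2].sum(axis=-1)

    def freq_B(self):
        """Frequency of the neutral B allele (pop1, pop2)."""
        return (self.x[..., 0] + self.x[..., 2],
                self.y[..., 0] + self.y[..., 2])


@dataclass(frozen=True)
class DivSelParams:
    """Simulation parameters; rates are per generation.

    Defaults follow the reference setting N = 1000 with 4Nμ = 0.01; ``r``
    is varied over a grid of scaled distances 4Nr when building trajectory
    grids.
    """

    N: int = 1000
    mu: float = 0.01 / 4000  # 4Nmu = 0.01
    r: float = 0.0
    m: float = 0.0125  # 4Nm = 50
    s: float = 0.1     # 4Ns = 400
    T_max: int | None = None  # default 8N
    reps: int = 1000
    init_mode: str = "new_mutation"
    standing_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        for name in ("mu", "r", "m", "s"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        if self.init_mode not in ("new_mutation", "standing_variation"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if not 0 < self.standing_threshold < 1:
            raise ValueError("standing_threshold must be in (0, 1)")

    @property
    def t_max(self) -> int:
        return 8 * self.N if self.T_max is None else self.T_max

    @classmethod
    def from_scaled(cls, fourNmu: float = 0.01, fourNr: float = 0.0,
                    fourNm: float = 50.0, fourNs: float = 400.0,
                    N: int = 1000, **kw) -> "DivSelParams":
        return cls(N=N, mu=fourNmu / (4 * N), r=fourNr / (4 * N),
                   m=fourNm / (4 * N), s=fourNs / (4 * N), **kw)


def equilibrium_frequency(m: float, s: float) -> float:
    """Deterministic migration–selection equilibrium frequency of the
    locally favoured allele."""
    if s <= 0:
        raise ValueError("s must be > 0")
    c = m / s
    return float(-c + 0.5 + np.sqrt(c * c + 0.25))


def _step_arrays(x: np.ndarray, y: np.ndarray, mu: float, r: float,
                 m: float, s: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic recursion on (..., 4) frequency arrays."""
    x1, x2, x3, x4 = (x[..., i] for i in range(4))
    y1, y2, y3, y4 = (y[..., i] for i in range(4))
    Dx = x1 * x4 - x2 * x3
    Dy = y1 * y4 - y2 * y3
    xa = x3 + x4  # freq of a in pop 1
    xA = x1 + x2
    ya = y3 + y4
    yA = y1 + y2
    nx = np.stack([
        (1 - mu) * x1 + mu * x2 - r * Dx - m * (x1 - y1) + s * x1 * xa,
        (1 - mu) * x2 + mu * x1 + r * Dx - m * (x2 - y2) + s * x2 * xa,
        (1 - mu) * x3 + mu * x4 + r * Dx - m * (x3 - y3) - s * x3 * xA,
        (1 - mu) * x4 + mu * x3 - r * Dx - m * (x4 - y4) - s * x4 * xA,
    ], axis=-1)
    ny = np.stack([
        (1 - mu) * y1 + mu * y2 - r * Dy - m * (y1 - x1) - s * y1 * ya,
        (1 - mu) * y2 + mu * y1 + r * Dy - m * (y2 - x2) - s * y2 * ya,
        (1 - mu) * y3 + mu * y4 + r * Dy - m * (y3 - x3) + s * y3 * yA,
        (1 - mu) * y4 + mu * y3 - r * Dy - m * (y4 - x4) + s * y4 * yA,
    ], axis=-1)
    return nx, ny


def deterministic_step(state: TwoLocusState,
                       params: DivSelParams) -> TwoLocusState:
    """One generation of the expected-frequency recursion."""
    nx, ny = _step_arrays(state.x, state.y, params.mu, params.r,
                          params.m, params.s)
    out = TwoLocusState.__new__(TwoLocusState)
    out.x, out.y = nx, ny
    return out


def _multinomial_resample(freqs: np.ndarray, n_gametes: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Multinomial drift on (..., 4) frequencies (clipped to the simplex)."""
    p = np.clip(freqs, 0.0, None)
    p = p / p.sum(axis=-1, keepdims=True)
    counts = rng.multinomial(n_gametes, p)
    return counts / n_gametes


def stochastic_generation(state: TwoLocusState, params: DivSelParams,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None
                          ) -> TwoLocusState:
    """Deterministic expectation followed by multinomial sampling of 2N
    gametes in each population."""
    if rng is None:
        rng = np.random.default_rng(seed)
    det = deterministic_step(state, params)
    out = TwoLocusState.__new__(TwoLocusState)
    out.x = _multinomial_resample(det.x, 2 * params.N, rng)
    out.y = _multinomial_resample(det.y, 2 * params.N, rng)
    return out


@dataclass
class TrajectoryGrid:
    """Mean locus-II statistics over replicates on a (4Nr × time) grid."""

    fourNr: np.ndarray             # (G,)
    time_points: np.ndarray        # (T,) generations since selection start
    pi_w1: np.ndarray              # (G, T) mean heterozygosity, pop 1
    pi_w2: np.ndarray
    pi_b: np.ndarray
    fst: np.ndarray                # 1 - mean(pi_w)/mean(pi_b)
    fst_se: np.ndarray             # delta-method Monte-Carlo SE
    reps: int = 0

    def pi_w(self) -> np.ndarray:
        return 0.5 * (self.pi_w1 + self.pi_w2)


def _neutral_prerun(params: DivSelParams, reps: int,
                    rng: np.random.Generator,
                    generations: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Drift–mutation–migration pre-run of locus II with locus I fixed for
    A.  Returns (X, Y) haplotype-frequency arrays of shape (reps, 4).

    Locus I is monomorphic throughout, so the linkage disequilibria vanish
    and the pre-run is independent of the recombination rate; a single
    pre-run therefore serves every 4Nr grid point.
    """
    gens = 20 * params.N if generations is None else generations
    X = np.zeros((reps, 4))
    Y = np.zeros((reps, 4))
    X[:, 0] = 1.0  # A-B fixed; mutation introduces b
    Y[:, 0] = 1.0
    p = replace(params, r=0.0, s=0.0)
    for _ in range(gens):
        nx, ny = _step_arrays(X, Y, p.mu, 0.0, p.m, 0.0)
        X = _multinomial_resample(nx, 2 * p.N, rng)
        Y = _multinomial_resample(ny, 2 * p.N, rng)
    return X, Y


def _het_stats(X: np.ndarray, Y: np.ndarray):
    qx = X[:, 0] + X[:, 2]  # B frequency
    qy = Y[:, 0] + Y[:, 2]
    pw1 = 2.0 * qx * (1.0 - qx)
    pw2 = 2.0 * qy * (1.0 - qy)
    pb = qx * (1.0 - qy) + qy * (1.0 - qx)
    return pw1, pw2, pb


def _ratio_fst_and_se(pw1, pw2, pb):
    """F_ST = 1 − mean(π_W)/mean(π_B) with a delta-method SE."""
    pw = 0.5 * (pw1 + pw2)
    mw, mb = pw.mean(), pb.mean()
    if mb <= 0:
        return np.nan, np.nan
    fst = 1.0 - mw / mb
    n = len(pw)
    cov = np.cov(pw, pb)
    var = (cov[0, 0] / mb**2 - 2 * mw * cov[0, 1] / mb**3
           + mw**2 * cov[1, 1] / mb**4) / n
    return fst, float(np.sqrt(max(var, 0.0)))


def neutral_equilibrium_stats(params: DivSelParams, reps: int | None = None,
                              seed: int | None = None,
                              generations: int | None = None):
    """Locus-II mean π_W, π_B, F_ST (with SE) at neutral mutation–drift–
    migration equilibrium (the s = 0 baseline)."""
    reps = params.reps if reps is None else reps
    rng = np.random.default_rng(seed)
    X, Y = _neutral_prerun(params, reps, rng, generations)
    pw1, pw2, pb = _het_stats(X, Y)
    fst, se = _ratio_fst_and_se(pw1, pw2, pb)
    return {"pi_w1": pw1.mean(), "pi_w2": pw2.mean(), "pi_b": pb.mean(),
            "fst": fst, "fst_se": se}


def _introduce_a(X0, Y0, params: DivSelParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Place one copy of a (frequency 1/2N) in population 2, on a B or b
    background chosen proportionally to their current frequencies."""
    X = X0.copy()
    Y = Y0.copy()
    f0 = 1.0 / (2 * params.N)
    qy = Y[:, 0] / np.maximum(Y[:, 0] + Y[:, 1], 1e-300)
    on_B = rng.random(len(Y)) < qy
    # remove one gamete's worth from the donor class, add the a haplotype
    donor = np.where(on_B, 0, 1)
    target = np.where(on_B, 2, 3)
    idx = np.arange(len(Y))
    Y[idx, donor] = np.maximum(Y[idx, donor] - f0, 0.0)
    Y[idx, target] += f0
    Y /= Y.sum(axis=1, keepdims=True)
    return X, Y


def _standing_phase(X0: np.ndarray, Y0: np.ndarray, params: DivSelParams,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Neutral (s = 0) drift of the introduced a allele until it reaches the
    standing-variation threshold in population 2; replicates that lose a are
    restarted from their introduction state.  Arrays are compacted to the
    still-running replicates as they finish."""
    reps = len(X0)
    Xs, Ys = X0.copy(), Y0.copy()
    idx = np.arange(reps)
    X, Y = X0.copy(), Y0.copy()
    Xi, Yi = X0.copy(), Y0.copy()  # restart states, aligned with idx
    guard, max_gens = 0, 20_000 * params.N
    while len(idx):
        guard += 1
        if guard > max_gens:
            raise RuntimeError("standing-variation phase failed to finish")
        nx, ny = _step_arrays(X, Y, params.mu, params.r, params.m, 0.0)
        X = _multinomial_resample(nx, 2 * params.N, rng)
        Y = _multinomial_resample(ny, 2 * params.N, rng)
        fa = X[:, 2] + X[:, 3] + Y[:, 2] + Y[:, 3]
        lost = fa <= 0
        if lost.any():
            X[lost] = Xi[lost]
            Y[lost] = Yi[lost]
        reached = (Y[:, 2] + Y[:, 3]) >= params.standing_threshold
        if reached.any():
            Xs[idx[reached]] = X[reached]
            Ys[idx[reached]] = Y[reached]
            keep = ~reached
            idx, X, Y, Xi, Yi = (idx[keep], X[keep], Y[keep],
                                 Xi[keep], Yi[keep])
    return Xs, Ys


def run_divergent_selection(params: DivSelParams,
                            fourNr_grid=None,
                            time_points=None,
                            seed: int | None = None,
                            condition_on_survival: bool = True
                            ) -> TrajectoryGrid:
    """Simulate locus-II trajectories around the divergently selected site.

    Per replicate: a neutral pre-run (20N generations, shared across the
    4Nr grid — see :func:`_neutral_prerun`) establishes mutation–drift
    equilibrium at locus II; at T = 0 the a allele enters population 2 at
    frequency 1/2N.  In ``standing_variation`` mode a first drifts
    neutrally until it reaches ``standing_threshold`` in population 2, and
    time is counted from the moment selection switches on.  Replicates that
    lose a entirely are restarted from their starting state (conditioning
    on establishment); set ``condition_on_survival=False`` to average over
    losses instead.  With s = 0 no conditioning is applied.

    Returns a :class:`TrajectoryGrid` of mean π_W (per population), π_B and
    ratio-of-means F_ST at each (4Nr, time point).
    """
    if fourNr_grid is None:
        fourNr_grid = np.array([0.1, 0.5, 2.0, 10.0, 50.0, 200.0])
    fourNr_grid = np.asarray(fourNr_grid, dtype=float)
    N = params.N
    if time_points is None:
        time_points = (np.array([0.01, 0.05, 0.1, 0.5, 1, 2, 4, 8]) * N)
    time_points = np.asarray(time_points).astype(int)
    t_max = int(time_points.max())
    reps = params.reps
    rng = np.random.default_rng(seed)
    condition = condition_on_survival and params.s > 0

    X0, Y0 = _neutral_prerun(params, reps, rng)
    X0, Y0 = _introduce_a(X0, Y0, params, rng)

    G, T = len(fourNr_grid), len(time_points)
    out = TrajectoryGrid(
        fourNr=fourNr_grid, time_points=time_points.astype(float),
        pi_w1=np.empty((G, T)), pi_w2=np.empty((G, T)),
        pi_b=np.empty((G, T)), fst=np.empty((G, T)),
        fst_se=np.empty((G, T)), reps=reps)

    tp_index = {int(t): j for j, t in enumerate(time_points)}
    for gi, fourNr in enumerate(fourNr_grid):
        p = replace(params, r=fourNr / (4.0 * N))
        if params.init_mode == "standing_variation":
            Xs, Ys = _standing_phase(X0, Y0, p, rng)
        else:
            Xs, Ys = X0, Y0
        X, Y = Xs.copy(), Ys.copy()
        store = np.empty((T, 3, reps))  # (pw1, pw2, pb) per time point
        counter = np.zeros(reps, dtype=np.int64)  # gens since selection on
        done = np.zeros(reps, dtype=bool)
        if 0 in tp_index:
            store[tp_index[0]] = np.stack(_het_stats(X, Y))
        guard, max_gens = 0, 100 * t_max + 100 * N
        while not done.all():
            guard += 1
            if guard > max_gens:
                raise RuntimeError("divergent-selection run failed to "
                                   "finish (conditioning too strict?)")
            nx, ny = _step_arrays(X, Y, p.mu, p.r, p.m, p.s)
            X = _multinomial_resample(nx, 2 * N, rng)
            Y = _multinomial_resample(ny, 2 * N, rng)
            fa = X[:, 2] + X[:, 3] + Y[:, 2] + Y[:, 3]
            lost = (fa <= 0) & ~done
            if condition and lost.any():
                X[lost] = Xs[lost]
                Y[lost] = Ys[lost]
                counter[lost] = 0
            advanced = ~done & (~lost if condition else np.ones(reps, bool))
            counter[advanced] += 1
            hit_any = False
            for t, j in tp_index.items():
                if t == 0:
                    continue
                hit = advanced & (counter == t)
                if hit.any():
                    if not hit_any:
                        pw1, pw2, pb = _het_stats(X, Y)
                        hit_any = True
                    store[j, 0, hit] = pw1[hit]
                    store[j, 1, hit] = pw2[hit]
                    store[j, 2, hit] = pb[hit]
            done |= counter >= t_max

        for j in range(T):
            pw1, pw2, pb = store[j]
            out.pi_w1[gi, j] = pw1.mean()
            out.pi_w2[gi, j] = pw2.mean()
            out.pi_b[gi, j] = pb.mean()
            fst, se = _ratio_fst_and_se(pw1, pw2, pb)
            out.fst[gi, j] = fst
            out.fst_se[gi, j] = se
    return out


def summarize_locus_stats(pw1, pw2, pb) -> dict:
    """Means with Monte-Carlo standard errors; F_ST as the ratio of means
    (consistent with the stored trajectory grids)."""
    pw1 = np.asarray(pw1, dtype=float)
    pw2 = np.asarray(pw2, dtype=float)
    pb = np.asarray(pb, dtype=float)
    if len(pw1) == 0:
        raise ValueError("need at least one replicate")
    n = len(pw1)
    fst, se = _ratio_fst_and_se(pw1, pw2, pb) if n > 1 else (
        1.0 - 0.5 * (pw1[0] + pw2[0]) / pb[0] if pb[0] > 0 else np.nan, 0.0)
    def mse(a):
        return float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {
        "pi_w1": float(pw1.mean()), "pi_w1_se": mse(pw1),
        "pi_w2": float(pw2.mean()), "pi_w2_se": mse(pw2),
        "pi_b": float(pb.mean()), "pi_b_se": mse(pb),
        "fst": fst, "fst_se": se, "reps": n,
    }
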