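"""Error-aware allele-frequency and SFS inference from pooled read counts.

Model
-----
A pool contains ``n`` chromosomes of which an unknown ``Y`` carry the focal
allele.  Each of the ``r`` reads at a site samples a chromosome uniformly
(with replacement) and reports its allele, flipped with sequencing-error
probability ``ε``.  The probability that one read shows the focal allele is
therefore ``(1−ε)·Y/n + ε·(1−Y/n)``, and the ordered-read likelihood of an
observed configuration with ``k`` focal reads is the product of the per-read
terms.  Because polarity (ancestral/derived) is unknown, folded quantities
average the likelihood of the observed reads and of their complement, which
is equivalent to averaging over ``Y`` and ``n−Y``.

The site frequency spectrum over folded allele-count classes
``0..⌊n/2⌋`` is estimated by an EM algorithm on the mixture
``P(k,r) = Σ_c φ_c · C(r,k) · P_f(k,r | c)``; the per-site maximum-likelihood
allele count ``ŷ = argmax_Y P(k,r|Y)`` gives point frequency estimates for
the genome scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "PoolModel", "FoldedSFS", "SiteFrequencyEstimate",
    "pool_read_likelihood", "folded_site_likelihood", "ml_site_frequency",
    "ml_frequency_lookup", "posterior_frequency_lookup",
    "posterior_site_frequency", "estimate_sfs_em",
    "nucleotide_diversity", "tajimas_d",
]


@dataclass(frozen=True)
class PoolModel:
    """Pool of ``n`` sampled chromosomes read with error rate ``epsilon``."""

    n: int = 40
    epsilon: float = 0.001

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("pool size n must be >= 2")
        if not 0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")

    def read_prob(self, y) -> np.ndarray:
        """Per-read probability of showing the focal allele given count y."""
        y = np.asarray(y, dtype=float)
        return (1.0 - self.epsilon) * y / self.n \
            + self.epsilon * (1.0 - y / self.n)


@dataclass
class FoldedSFS:
    """Probability vector over folded allele-count classes 0..⌊n/2⌋."""

    n: int
    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if len(self.phi) != self.n // 2 + 1:
            raise ValueError("phi must have n//2 + 1 entries")
        if (self.phi < -1e-12).any():
            raise ValueError("phi entries must be non-negative")
        if abs(self.phi.sum() - 1.0) > 1e-9:
            raise ValueError("phi must sum to 1")

    @property
    def prop_polymorphic(self) -> float:
        return float(1.0 - self.phi[0])

    def expected_counts(self, n_sites: int) -> np.ndarray:
        return self.phi * n_sites


@dataclass(frozen=True)
class SiteFrequencyEstimate:
    y_hat: int
    freq: float
    loglik: float
    coverage: int


def _check_kr_y(k: int, r: int, y: int, n: int) -> None:
    if not 0 <= k <= r:
        raise ValueError(f"need 0 <= k <= r, got k={k}, r={r}")
    if not 0 <= y <= n:
        raise ValueError(f"need 0 <= Y <= n, got Y={y}, n={n}")


def _loglik(k, r, y, model: PoolModel):
    """log P(ordered reads | Y) — vectorised over any argument."""
    p = model.read_prob(y)
    k = np.asarray(k, dtype=float)
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = k * np.log(p) + (r - k) * np.log1p(-p)
        # 0 * log 0 -> 0 by convention
        out = np.where((k == 0) & (p == 0.0), (r - k) * np.log1p(-p), out)
        out = np.where((r - k == 0) & (p == 1.0), k * np.log(p), out)
    return out


def pool_read_likelihood(k: int, r: int, Y: int, model: PoolModel) -> float:
    """Ordered-read probability of ``k`` focal reads out of ``r`` given
    allele count ``Y`` (no binomial coefficient)."""
    _check_kr_y(k, r, Y, model.n)
    return float(np.exp(_loglik(k, r, Y, model)))


def folded_site_likelihood(k: int, r: int, Y: int, model: PoolModel) -> float:
    """½·P(reads|Y) + ½·P(complemented reads|Y): the folded likelihood used
    when polarity is unknown."""
    _check_kr_y(k, r, Y, model.n)
    return 0.5 * (pool_read_likelihood(k, r, Y, model)
                  + pool_read_likelihood(r - k, r, Y, model))


def ml_site_frequency(k: int, r: int, model: PoolModel) -> SiteFrequencyEstimate:
    """Integer-ML allele count: argmax over Y in 0..n of the read likelihood.

    Ties are broken toward the boundary nearer the raw read fraction k/r.
    """
    if r < 1:
        raise ValueError("coverage r must be >= 1")
    _check_kr_y(k, r, 0, model.n)
    ys = np.arange(model.n + 1)
    ll = _loglik(k, r, ys, model)
    best = np.flatnonzero(ll >= ll.max() - 1e-12)
    y_hat = int(best.min() if k / r <= 0.5 else best.max())
    return SiteFrequencyEstimate(y_hat=y_hat, freq=y_hat / model.n,
                                 loglik=float(ll[y_hat]), coverage=int(r))


def ml_frequency_lookup(max_r: int, model: PoolModel) -> np.ndarray:
    """Table ``yhat[r, k]`` of integer-ML allele counts for all 0<=k<=r<=max_r.

    Lets whole-genome scans estimate frequencies with one fancy-indexing
    operation; entries with k > r are n+1 (invalid marker).
    """
    ys = np.arange(model.n + 1, dtype=float)
    p = model.read_prob(ys)
    logp = np.log(p, out=np.full_like(p, -np.inf), where=p > 0)
    logq = np.log1p(-p, out=np.full_like(p, -np.inf), where=p < 1)
    table = np.full((max_r + 1, max_r + 1), model.n + 1, dtype=np.int16)
    for r in range(1, max_r + 1):
        k = np.arange(r + 1, dtype=float)
        with np.errstate(invalid="ignore"):
            ll = (np.where(k[:, None] > 0,
                           k[:, None] * logp[None, :], 0.0)
                  + np.where((r - k)[:, None] > 0,
                             (r - k)[:, None] * logq[None, :], 0.0))
        # tie-break toward boundary nearer k/r
        lo = np.argmax(ll, axis=1)  # first maximiser
        hi = model.n - np.argmax(ll[:, ::-1], axis=1)  # last maximiser
        table[r, :r + 1] = np.where(k / r <= 0.5, lo, hi)
    return table


def _unfolded_prior(prior: "FoldedSFS") -> np.ndarray:
    """Symmetric unfolded prior over Y = 0..n implied by a folded SFS
    (each folded class splits its mass equally over its two members)."""
    n = prior.n
    pi = np.zeros(n + 1)
    for c, mass in enumerate(prior.phi):
        if 2 * c == n:
            pi[c] = mass
        else:
            pi[c] += mass / 2.0
            pi[n - c] += mass / 2.0
    return pi


def posterior_frequency_lookup(max_r: int, model: PoolModel,
                               prior: "FoldedSFS") -> np.ndarray:
    """Table ``p_hat[r, k]`` of posterior-mean allele frequencies
    E[Y/n | k, r] under a folded-SFS prior.

    This is the shrinkage estimator implied by SFS-based EM inference:
    the prior concentrates mass on the monomorphic and rare classes, which
    suppresses the read-sampling noise that otherwise inflates per-site
    differentiation at low coverage.  Entries with k > r are NaN.
    """
    n = model.n
    pi = _unfolded_prior(prior)
    pi = np.maximum(pi, 1e-300)
    ys = np.arange(n + 1, dtype=float)
    p = model.read_prob(ys)
    logp = np.log(p, out=np.full_like(p, -np.inf), where=p > 0)
    logq = np.log1p(-p, out=np.full_like(p, -np.inf), where=p < 1)
    table = np.full((max_r + 1, max_r + 1), np.nan)
    logpi = np.log(pi)
    for r in range(1, max_r + 1):
        k = np.arange(r + 1, dtype=float)
        with np.errstate(invalid="ignore"):
            ll = (np.where(k[:, None] > 0, k[:, None] * logp[None, :], 0.0)
                  + np.where((r - k)[:, None] > 0,
                             (r - k)[:, None] * logq[None, :], 0.0))
        w = ll + logpi[None, :]
        w -= w.max(axis=1, keepdims=True)
        post = np.exp(w)
        post /= post.sum(axis=1, keepdims=True)
        table[r, :r + 1] = post @ (ys / n)
    return table


def posterior_site_frequency(k: int, r: int, model: PoolModel,
                             prior: "FoldedSFS") -> float:
    """Posterior-mean allele frequency at a single site (see
    :func:`posterior_frequency_lookup`)."""
    if r < 1:
        raise ValueError("coverage r must be >= 1")
    _check_kr_y(k, r, 0, model.n)
    return float(posterior_frequency_lookup(r, model, prior)[r, k])


def estimate_sfs_em(records, model: PoolModel, tol: float = 1e-8,
                    max_iter: int = 1000) -> FoldedSFS:
    """EM estimate of the folded SFS from (k, r) count pairs.

    E-step: posterior over folded classes given current φ.  M-step: φ set to
    the mean posterior.  Iterates until ``max |Δφ| < tol`` or ``max_iter``;
    the observed-data log-likelihood is non-decreasing and is stored on the
    result as ``.loglik_path``.
    """
    arr = np.asarray(list(records) if not isinstance(records, np.ndarray)
                     else records, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("estimate_sfs_em needs at least one site")
    k, r = arr[:, 0], arr[:, 1]
    if (k < 0).any() or (k > r).any() or (r < 1).any():
        raise ValueError("invalid (k, r) records")

    n = model.n
    n_fold = n // 2 + 1
    uniq, weights = np.unique(arr, axis=0, return_counts=True)
    ku, ru = uniq[:, 0].astype(float), uniq[:, 1].astype(float)

    classes = np.arange(n_fold)
    # folded likelihood for class c: average over members {c, n-c}
    ll_lo = _loglik(ku[:, None], ru[:, None], classes[None, :], model)
    ll_hi = _loglik(ku[:, None], ru[:, None], (n - classes)[None, :], model)
    lik = 0.5 * (np.exp(ll_lo) + np.exp(ll_hi))
    lik = np.where(classes[None, :] * 2 == n, np.exp(ll_lo), lik)
    log_binom = (gammaln(ru + 1) - gammaln(ku + 1) - gammaln(ru - ku + 1))
    lik *= np.exp(log_binom)[:, None]

    phi = np.full(n_fold, 1.0 / n_fold)
    loglik_path: list[float] = []
    w = weights.astype(float)
    wsum = w.sum()
    for _ in range(max_iter):
        mix = lik * phi[None, :]
        site_tot = mix.sum(axis=1)
        loglik_path.append(float(np.dot(w, np.log(site_tot))))
        post = mix / site_tot[:, None]
        new_phi = (w[:, None] * post).sum(axis=0) / wsum
        delta = np.abs(new_phi - phi).max()
        phi = new_phi
        if delta < tol:
            break
    phi = np.clip(phi, 0.0, None)
    phi /= phi.sum()
    sfs = FoldedSFS(n=n, phi=phi)
    sfs.loglik_path = np.asarray(loglik_path)  # type: ignore[attr-defined]
    sfs.n_iter = len(loglik_path)  # type: ignore[attr-defined]
    return sfs


def nucleotide_diversity(sfs_or_freqs, n: int | None = None,
                         L: float | None = None) -> float:
    """Per-bp nucleotide diversity π with the n/(n−1) sample correction.

    ``sfs_or_freqs`` is either an array of per-site focal-allele frequencies
    (π = Σ [n/(n−1)]·2p(1−p) / L) or a :class:`FoldedSFS`, in which case the
    expected per-site heterozygosity under φ is scaled by the proportion of
    sites (L is then the total site count and each class c contributes at
    frequency c/n).
    """
    if isinstance(sfs_or_freqs, FoldedSFS):
        sfs = sfs_or_freqs
        n = sfs.n
        c = np.arange(len(sfs.phi))
        p = c / n
        het = (n / (n - 1)) * 2.0 * p * (1.0 - p)
        return float(np.dot(sfs.phi, het))  # already per site
    p = np.asarray(sfs_or_freqs, dtype=float)
    if n is None or n < 2:
        raise ValueError("need pool size n >= 2")
    if L is None:
        raise ValueError("need total site count L")
    n_poly = np.count_nonzero((p > 0) & (p < 1))
    if L < n_poly:
        raise ValueError("L must be >= number of polymorphic sites")
    het = (n / (n - 1)) * 2.0 * p * (1.0 - p)
    return float(het.sum() / L)


def tajimas_d(sfs_counts, n: int) -> float:
    """Tajima's D from an SFS of segregating-site counts.

    ``sfs_counts[i]`` is the number of sites with allele count ``i+1``
    (folded or unfolded — the pairwise-difference estimator
    Σ ξ_c·c(n−c)/C(n,2) is invariant under folding).  Returns ``nan`` when
    there are no segregating sites.
    """
    xi = np.asarray(sfs_counts, dtype=float)
    S = xi.sum()
    if S <= 0:
        return float("nan")
    c = np.arange(1, len(xi) + 1, dtype=float)
    if len(xi) > n - 1:
        raise ValueError("sfs_counts longer than n-1 classes")
    pi = float((xi * c * (n - c)).sum() / (n * (n - 1) / 2.0))

    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))
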