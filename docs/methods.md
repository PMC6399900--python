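# Methods

This note documents the models behind `poolscan`, the estimators and their
numerical treatment, what the synthetic-data generator does and does not
emulate, and the places where the design was genuinely open.

## Pooled read model and SFS inference

A pool of `n` chromosomes (default 40, i.e. 20 diploids per species) is
sequenced to depth `r` at a site; `Y` chromosomes carry the focal allele
and each read reports its chromosome's allele with error probability ε
(default 0.001, overridable everywhere). Reads are exchangeable, so the
ordered-read likelihood is a product of per-read terms
`(1−ε)Y/n + ε(1−Y/n)` (focal read) and `(1−ε)(1−Y/n) + εY/n` (other).
All likelihoods are evaluated in log space; `0·log 0` terms are defined as
0 so that ε = 0 boundaries are exact. Because ancestral state is unknown,
folded quantities average the likelihood of the observed reads and their
complement, which equals averaging over `Y` and `n−Y`.

The folded SFS `φ` over classes `0…⌊n/2⌋` is estimated by EM on the
mixture over classes. Convergence: `max|Δφ| < 1e-8` or 1000 iterations;
the observed-data log-likelihood is recorded per iteration and is
asserted non-decreasing in tests. Sites are collapsed to unique `(k, r)`
pairs first, which makes the E-step cost independent of genome size.

### Two frequency estimators

* **Integer ML**: `ŷ = argmax_Y P(k,r|Y)`, ties broken toward the boundary
  nearer `k/r`. Used for fixed-difference calling (a fixed difference is
  `ŷ = n` in one pool and `ŷ = 0` in the other, coverage ≥ 20 in both) and
  as the genome-scan default.
* **Posterior mean** under the EM-estimated folded SFS (mass of each
  folded class split equally over its two unfolded members). This is the
  shrinkage estimator implied by SFS-based inference. It matters for
  per-site F_ST: raw ML frequencies carry read-sampling noise of order
  `1/r`, which biases per-site `1 − π_W/π_B` upward by roughly `1/r` (≈
  +0.025 at 20–30×); the posterior mean suppresses that noise, and with
  it the bias, reproducing the near-zero panmixia behaviour of the data.
  The per-site F_ST summary, the simulated null distribution and the
  power analysis therefore use posterior-mean frequencies, each with a
  prior estimated from the same kind of data being analysed.

Nucleotide diversity applies the `n/(n−1)` sample correction,
`π = Σ [n/(n−1)]·2p̂(1−p̂)/L`; whether the original analyses applied this
correction is not documentable, so it is stated here and applied
throughout. Tajima's D uses the standard constants derived from `n`; the
pairwise-difference term `Σ ξ_c·c(n−c)/C(n,2)` is invariant under folding,
so folded counts are accepted.

## Genome scan

Windows are 10 kb tiled every 5 kb (the 2-kb increment variant is an
argument); a window is reported when ≥ 50% of its table sites have ≥ 20
reads in both species. Window F_ST is the ratio of window-summed π's
(ratio of averages), which is robust to low-information sites; per-site
F_ST is undefined (NaN) where the estimated π_B is 0. Negative F_ST is
never clamped. Note that ratio-of-sums window F_ST under panmixia has a
small positive Jensen bias when windows contain few, genealogically
correlated sites (≈ +0.02 at 20× with ~10 segregating sites per
non-recombining window); this is a property of the estimator, not an
error, and it cancels from rank-based screening and from null-vs-observed
comparisons that use the same estimator on both sides.

## Differentiated-region calling

1. Threshold = the empirical `(1−q)` quantile (lower interpolation) of
   window F_ST, `q = 0.001`; strictly greater windows are selected, so
   ties are excluded and `q = 0` selects nothing.
2. Selected windows whose spans overlap or abut merge into candidate
   peaks.
3. **Peak shape**: on each side of the merged span the minimum F_ST over
   the nearest 3 windows fully outside the span must fall below the
   genome-wide 90th-percentile background value. The minimum-over-3 form
   is deliberate: a single flanking window is itself a noisy F_ST
   estimate, and demanding that *both* immediate flanks sit below the
   background 90th percentile would falsely reject ≈ 19% of genuine
   isolated peaks (each background flank exceeds its own q90 10% of the
   time). Requiring the signal to return to background within ~20 kb on
   each side keeps the intent — short peaks pass, broad plateaus (the
   background-selection signature) fail.
4. A candidate is called only if it contains ≥ 1 fixed difference.

Window neutrality p-values are add-one empirical tail probabilities
against the simulated panmixia null; the FDR estimate is
`min(1, p·M/k)` (expected false positives over discoveries), documented
as an estimate rather than a step-up procedure.

## Panmixia null and power

The null replicates the estimation pipeline end to end: one
non-recombining 10-kb coalescent window of 80 chromosomes (expansion
demography), a random 40/40 split, pooled reads at fixed 20× (the
variance-maximising depth) with ε, frequency re-estimation, window F_ST.
The coalescent engine is msprime behind the module interface; samples are
drawn as diploids so that sizes follow the diploid convention
(`θ = 4N_cur μ` per bp, pairwise E[T] = 2N).

The default expansion demography — instantaneous growth from
N_anc = 2×10⁴ to N_cur = 10⁶ at 7,500 generations ago — is a documented
stand-in chosen to produce the observed qualitative SFS behaviour (~70%
singletons in a sample of 80, strongly negative Tajima's D); the genuinely
fitted values were not available. θ defaults to 0.004/bp, giving a few
segregating sites per kb at desk scale rather than a realistic cichlid
density; all SFS-shape and calibration conclusions are insensitive to this
scale choice.

Detection power: a two-deme island model with migration tuned through
`F_ST = 1/(1+8Nm)` to a target; the test statistic is the genome-average
window F_ST over 30 independent 10-kb regions at 34×; the critical value
is the `(1−α)` quantile of the same statistic under panmixia. Power at a
target of 0 is α by construction (verified), and power rises with the
target.

## Two-locus divergent-selection simulator

Haplotype frequencies (A-B, A-b, a-B, a-b) in two populations follow the
deterministic recursion with symmetric mutation at locus II, recombination
through the linkage disequilibria `D_x`, `D_y`, symmetric migration, and
additive divergent selection of opposite sign in the two populations. The
update conserves the frequency simplex algebraically (asserted to 1e-12)
and commutes with the swap-populations/rename-alleles symmetry. Drift is
per-population multinomial resampling of 2N gametes around the
deterministic expectation (the drift scheme was an open choice; multinomial
Wright–Fisher sampling is the standard one). Tiny negative intermediate
frequencies that the linearised selection terms can produce are clipped to
0 before resampling.

Defaults: N = 1000, 4Nμ = 0.01, 4Nm = 50, 4Ns = 400, 8N generations,
recorded time points {0.01, 0.05, 0.1, 0.5, 1, 2, 4, 8}×N, 4Nr grid over
0.1–200.

* **Pre-run.** Locus I is monomorphic during the neutral pre-run, so the
  linkage disequilibria vanish and the pre-run is independent of r: one
  20N-generation pre-run is shared across the whole 4Nr grid.
* **Initialisation.** `new_mutation`: one copy of a (frequency 1/2N) in
  population 2, placed on a B or b background proportionally to their
  frequencies. `standing_variation`: a drifts neutrally (with migration
  and recombination) until it reaches 20% in population 2, then selection
  switches on; time is counted per replicate from that moment.
* **Conditioning.** Replicates that lose a entirely are restarted from
  their starting state — the trajectories are conditioned on
  establishment, which is what makes "the footprint of a successful
  divergent-selection event" well defined. With s = 0 no conditioning is
  applied.
* **Outputs.** Locus-II population heterozygosities (π_W per population,
  π_B between) averaged over replicates; F_ST as the ratio of means, with
  a delta-method Monte-Carlo SE. Heterozygosity (not sampled-sequence
  diversity) is the recorded quantity; at these θ values the distinction
  is a second-order effect.

A quantitative note on attainable differentiation: at m/s = 0.125 the
migration–selection equilibrium is p̂ = 0.890, so locus I itself
differentiates to frequencies 0.890/0.110, capping F_ST at a perfectly
linked neutral site near `1 − 2p̂q̂/(p̂² + q̂²) ≈ 0.76` — and that only as
π_B accumulates over several N generations; π_W of the non-swept
population never drops, so F_ST near the target is ≈ 0.3 shortly after
the sweep and ≈ 0.6 by 8N generations. Expectations of near-total
differentiation (F_ST > 0.9) at these parameter values are not achievable
in this model; they would require m/s ≲ 0.03.

## Synthetic-data generator

The generator produces a full two-species Pool-seq site table with known
truth, emulating: near-panmictic background (two-deme island model with
4N(t)m(t) = 50 held constant through the expansion, so E[F_ST] matches the
constant-size closed form 1/(1+8Nm) ≈ 0.0099), expansion-shaped folded SFS
with singleton excess, Poisson 34× coverage of n = 40 per species with
ε = 0.001, and 21 planted DRs of 14–28 kb containing 1–7 fixed differences
placed near each DR centre.

Scale decisions (all deliberate, recorded once):

* Genome 24 × 20 Mb: the top-0.1% screen then has a ~96-window quota,
  matching the proportionality between genome size and the 21 DRs in the
  motivating study.
* Per-bp mutation rate 3×10⁻⁹ on the expansion demography → ~3 segregating
  sites per kb (a scaled-down density that keeps the table at ~3 M rows);
  monomorphic anchor sites every 500 bp carry the ≥50%-covered window
  rule, standing in for the all-sites table of a real pileup. The
  coverage fraction is therefore relative to assessed sites, not to every
  bp.
* Background recombination 2.5×10⁻⁹/bp, giving genealogy correlation of a
  few kb — far below the window size, as in the real data. (A much lower
  rate produces hundreds-of-kb single-genealogy blocks whose window F_ST
  reaches ≈ 0.2, i.e. spurious megabase-scale differentiated background
  that the emulated study does not have.)
* DR interiors follow the two-locus simulator's profile (new-mutation
  mode, 4Ns = 400, 4Nm = 50, T = 0.5N, computed at generation time from
  ~300 replicates): at scaled distance `4Nr(d)` from the DR centre a site
  becomes strongly differentiated with probability given by the profile's
  excess F_ST, is silenced (monomorphic) with probability given by the
  π_W reduction, or keeps its background frequencies. The 4Nr-per-bp
  scale puts the neutral end of the profile (4Nr = 200) a quarter of the
  DR length from the centre, so each planted interval contains its own
  decay flanks.

What the generator does **not** emulate: read mapping artefacts
(mapability, paralogy, indel realignment), base-quality structure and the
bias annotations the filters accept, linkage over tens of kb within DRs
at the haplotype level (DR sites are drawn independently given the
profile), and realistic per-bp polymorphism density. Passing the pipeline
tests on this generator therefore demonstrates the statistical machinery
(estimation, screening, peak calling, calibration) under the study's
stated conditions — not robustness to alignment artefacts.

## Numerical and policy details

* Coordinates: inputs 1-based (pileup convention); all exported intervals
  0-based half-open BED. The focal allele is the global minor across both
  pools, ties broken alphabetically.
* Site filters: ±9 bp indel masks (union over species), ≥3-nucleotide
  removal, named coverage presets (scan 20–200×, sfs 80–200×, site-F_ST
  40–200×), bias p-value cuts applied only where the annotation exists.
  Filtering is idempotent and a new table is always returned.
* Fixed-difference calling in the end-to-end pipeline uses the scan
  coverage floor (20×): at Poisson 34× the probability that a site has
  ≥ 40× in both pools is ≈ 3%, so a 40× floor would discard nearly all
  genuinely fixed sites.
* All stochastic components accept a seed and are reproducible; seeds
  derived internally stay below 2³¹.
* Problem sizes in the test suite (10⁴ neutral-calibration replicates,
  10³ hitchhiking replicates, 10⁵ sites for the EM and panmixia checks,
  one default synthetic genome) were chosen so the whole suite runs on a
  single CPU in about ten minutes while keeping Monte-Carlo error well
  inside the asserted tolerances.
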