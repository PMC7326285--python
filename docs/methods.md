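# Methods

## The model

`introsweep` detects *adaptive introgression sweeps*: the fixation in a
recipient species of a beneficial allele acquired by hybridization from a
diverged donor. The method uses polymorphism data from the recipient only —
no donor sequence is required.

### Star-like sweep phase

Backward in time, a lineage sampled at distance `d` bp from the selected
site escapes the sweep by recombining onto the ancestral background with
probability

    P_e = 1 - exp(-alpha * d),      alpha = (r / s) * ln(2N),

where `r` is the per-site recombination rate, `s` the heterozygote
selection coefficient and `N` the diploid population size. Lineages escape
independently, and all non-escaping lineages coalesce instantaneously on
the founding introgressed haplotype (the star-like approximation). The
number of escapees among `n` sampled lineages is binomial(`n`, `P_e`).

### The volcano

For a pair of lineages the genealogical cases and the resulting expected
heterozygosity are

    H_classic = (1 - P_B) * theta                    (de novo sweep)
    H_intro   = P_bb * theta + P_Bb * D              (introgression sweep)

with `P_B = (1-P_e)^2`, `P_Bb = 2 P_e (1-P_e)`, `P_bb = P_e^2`, `theta =
4*N*mu`, and `D = (2 T_d + 1) theta` the expected recipient-donor
divergence (`T_d` in units of 4N generations). A pair split by the sweep
coalesces only in the donor-recipient ancestor, converting divergence into
excess intermediate-frequency polymorphism: heterozygosity overshoots the
background on both flanks (the "volcano"), while a narrow central valley
stays depleted.

In scaled distance `s = alpha*d` the geometry is closed-form (`D > theta`):

* valley edge (H = theta):   `s = ln((2D - theta) / (2D - 2 theta))`
* peak position:             `s = ln((2D - theta) / (D - theta))  -> ln 2`
* peak height:               `H* = D^2 / (2D - theta)`, relative excess
  `(H* - theta)/theta = 4 T_d^2 / (4 T_d + 1)`
* 10%-decay flank:           `s_peak + ln(10 / (10 - 3 sqrt(10)))  -> ~3.7`

The flank constant is exact for every `D > theta`: substituting
`w = v / v_peak` with `v = exp(-s)` into `H(s) - theta = (H* - theta)/10`
gives `w^2 - 2w + 1/10 = 0`, whose outer root is `w = 1 - 3/sqrt(10)`.
The property suite verifies both this identity and the numeric argmax
against the closed forms.

### The transformed site frequency spectrum

The background (null) model is the genome-wide unnormalized SFS `S_i(n)`,
whose subsamples follow the hypergeometric projection

    S_j(k) = sum_{i>=j} S_i(n) C(i,j) C(n-i, k-j) / C(n,k).

From it we use `theta_pi = S_1(2)` (pairwise estimator), `theta_L =
(1/(n-1)) sum i S_i`, and the recipient-to-ancestor divergence `D_o =
S_n + (1/n) sum_{i<n} i S_i = S_1(1)`. After a sweep at distance `d`, with
`P_e(k)` the escape-count mass,

    S'_i = sum_{k=i+1}^{n} P_e(k) S_i(k) + P_e(n-i) D/2 + P_e(i) D/2,
    S'_n = (D_o - D/2) sum_{0<k<n} P_e(k) + D_o (P_e(0) + P_e(n)),

for polymorphic classes `i` and the recipient-lineage fixed-difference
class `n`. Conditioning on the site being informative cancels the mutation
rate, exactly as for the background. The model neglects the
within-recipient coalescent time relative to the divergence times, so the
far-field (`alpha*d -> inf`) limit of `S'_n` is `D_o` rather than the
background `S_n`; consequences are discussed under *Numerical choices*.

### Composite likelihood ratio

With informative sites `X_l` at distances `d_l` from a test site, the scan
statistic is

    T1 = 2 [ max_{alpha, D} sum_l ln q'_{X_l}(alpha, d_l, D) - sum_l ln q_{X_l} ],

where `q` and `q'` are the background and transformed conditionals
(with fixed differences; `p`/`p'` in polymorphic-only mode). `D` is
searched over a grid — by default multiples of `theta_pi` capped at
`2 D_o` (polarized fixed differences) or `D_o'` (unpolarized) — and, for
each `D`, `alpha` by a log-spaced grid over `[1e-8, 1e-1]` per bp with
golden-section refinement (tolerance 1e-3 in ln alpha). Sites with
`alpha*d > 12` carry essentially no sweep information and contribute the
null term to both models. Output reports both `T1` (column `LR`) and
`T1/2` (column `lnCLR`), since candidate thresholds are conventionally
phrased on ln(CLR); the factor-2 convention is ambiguous in the field, so
both are written.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `alpha` bounds | 1/bp | `[1e-8, 1e-1]` | brackets `(r/s) ln 2N` for `r` in 1e-9..1e-7, `s` in 1e-4..0.1, `N` in 1e3..1e6 |
| `alpha_grid_points` | – | 64 | coarse log grid before golden refinement |
| `ad_cutoff` | scaled distance | 12 | beyond it `q'` is background to ~1e-5 relative |
| `D` grid | per-site divergence | `k * theta_pi <= 2 D_o` | mirrors the default of the original scan design |
| peak threshold | ln(CLR) | 20 | far-tail under the null (observed neutral maxima are ~5–9) |
| peak separation | bp | 15 000 | center-to-center thinning of candidate peaks |
| half-width floor | bp | 5 000 | with `r = 1e-8`, `N_e = 1e4` this equals `2 N_e s >= 2.7` |
| site-gap quantile | – | 0.9995 | rejects peaks inside data deserts |

## The synthetic-data generator

`simulate_sites` draws data from exactly the probabilistic model the scan
fits: each bp is independently informative with probability
`sum_i S_i` (the background spectrum read as per-site probabilities), and
an informative site's class follows the background conditional `q` — or
the transformed conditional `q'(alpha, d, D)` within scaled distance 12 of
a planted sweep. Defaults are `theta = 0.002`, `n = 40`, `D_o = 0.0125`
(per site), matching the diversity used in the pairwise-footprint
analysis, the sample size of the power experiments, and a human-like
outgroup divergence.

What the generator deliberately omits: linkage disequilibrium (sites are
independent, as the composite likelihood assumes), sweep-trajectory
stochasticity (early recombination events that truncate real volcanoes),
demography, admixed backgrounds, and mutation-rate variation. Passing
recovery tests on these tables therefore demonstrates correctness of the
likelihood machinery under its own assumptions — not robustness to the
coalescent correlation structure of real genomes, for which external
simulators would be needed.

One consequence of holding the informative-site *density* at the
background value: near a planted sweep the per-bp class-1 rate is
`(sum S_i) * q'_1(d)`, not `S'_1(d)` itself. The Monte-Carlo agreement
test therefore checks the class-1 fraction among informative sites per
window against `q'_1(d)` — whose numerator is exactly the closed-form
heterozygosity — rather than a raw per-bp rate.

## Numerical choices

* **Scaled-distance tables.** The transformed conditionals depend on
  `(alpha, d)` only through `s = alpha*d`. The scan precomputes, per `D`,
  per-class log-probability differences on a 4097-point uniform `s`-grid
  over `[0, 12]` and evaluates likelihoods by linear interpolation inside
  a compiled kernel; interpolation error is O((12/4096)^2) ≈ 1e-6 per
  site. `composite_loglik_alt` evaluates the transform exactly with no
  tables and is cross-checked against the kernel path in the tests.
* **Escape-count masses** are computed as `C(n,k) u^k (1-u)^(n-k)`
  directly, keeping the `n = 2` transform bit-consistent with the
  closed-form heterozygosity (verified to relative error < 1e-12 over
  1000 random parameter triples).
* **Binomial coefficients** are exact integers for `n <= 30` and
  log-gamma based above, for large sequencing panels.
* **Underflow**: per-site log probabilities are floored at `ln(1e-300)`;
  all accumulation is in log space. `LR` is clipped at 0 when the optimum
  cannot beat the null (the null is nested in the large-`alpha` limit).
* **Coincident sites**: a data site at the test position is evaluated at
  `d = 1` bp, the model's resolution, avoiding the 0/0 in the
  polymorphic-only conditional.
* **Ties across the `D` grid** resolve toward smaller `D` (deterministic
  and conservative). Test sites are at `start + j * span/(m+1)`, rounded
  to integer bp; block mode partitions this grid into contiguous chunks,
  and concatenated block scans are bit-identical to the unsplit scan.
* **Truncation.** In polymorphic-only mode the transformed conditional
  beyond `alpha*d = 12` equals the background to ~1e-5, so doubling the
  cutoff leaves the LR unchanged to < 0.1%. With fixed differences the
  class-n far field tends to `D_o` rather than `S_n` (see above), a
  KL divergence of order 1e-3 nats per site; doubling the cutoff then
  shifts the LR by a small systematic amount (measured ~0.5% on planted
  data). The cutoff at 12 keeps this mismatch out of the statistic.
* **Needle-shaped position profile.** The likelihood as a function of the
  *test position* drops sharply once the test site leaves the (often
  sub-kilobase) model valley; this is why fine test-site grids (every
  250–1000 bp) are standard for this statistic. `refine_scan` runs a
  coarse grid and then a 1-kb grid around the coarse argmax, equivalent
  to a uniformly fine scan near the optimum at a fraction of the cost.
* **Null LR levels.** Under the null with the default wide `alpha`
  bounds, windows as small as `12/alpha_max = 120` bp allow few-site
  overfits, putting the median per-test-site LR near 2; capping the
  search at `alpha <= 1e-3` (windows of >= 12 kb) brings the median to 0.
  Either way the distribution sits far below the `lnCLR >= 20` candidate
  threshold (largest observed neutral `lnCLR` over 10^4 test sites: ~9).

## Problem sizes used by the test suite

Replicate experiments run at sizes chosen to exercise the full pipeline
on a desktop: fifty 1 Mb replicates with a planted sweep (`alpha` set for
a ~50 kb volcano, `D = 9 theta`, `n = 40`) for parameter recovery, one
hundred 1 Mb neutral replicates for null calibration, and 10^4 pairwise
replicates of a 160 kb region for the Monte-Carlo volcano comparison.
Scans in these experiments use a 100-site coarse grid with 1-kb
refinement and a 32-point `alpha` grid.

## Known limitations

* Star-like approximation only: it overestimates the volcano height, so
  fitted `D` is biased downward; treat `alpha_hat`, `D_hat` as fit
  parameters, not unbiased estimators of `s` or divergence time.
* Model 1 only: the within-recipient coalescent time on the
  fixed-difference branch is neglected (the `D_o` far-field limit above).
* Complete, recently finished sweeps: no incomplete or very old sweeps,
  no within-donor standing-variation modelling (hard and soft
  introgression sweeps leave similar volcanoes regardless).
* Polarized data required; folded spectra are rejected.
* Composite likelihood: `LR` values are not chi-square distributed and
  carry no p-values; candidate calling is outlier-based by design.
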