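"""The introgression-sweep model.

An adaptive allele introduced by hybridization from a diverged donor
species drags linked donor haplotype into the recipient population as it
fixes. Backward in time, a lineage sampled at recombination distance
``R = r d`` from the selected site escapes the sweep with probability
``P_e = 1 - exp(-alpha d)`` where ``alpha = (r/s) ln(2N)`` (star-like
approximation). Escaped lineage pairs coalesce neutrally; a pair split by
the sweep coalesces only in the donor-recipient ancestor, turning
divergence ``D = (2 T_d + 1) theta`` into excess intermediate-frequency
polymorphism. The result is a "volcano": a narrow central valley of
reduced diversity flanked by shoulders where heterozygosity overshoots
the background.

Two free parameters describe the footprint: ``alpha`` (per-bp sweep
strength; sets the width) and ``D`` (donor divergence; sets the height).
This module provides the pairwise-heterozygosity curve and its geometry in
closed form, and the transformed site frequency spectrum under the sweep
for arbitrary sample size, which the composite-likelihood scan consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from .sfs import (
    ConditionalSFS,
    UnnormalizedSFS,
    divergence_outgroup,
    subsample_matrix,
)

__all__ = [
    "SweepParameters",
    "SelectionContext",
    "SweepCaseProbabilities",
    "VolcanoGeometry",
    "FLANK_DECAY_CONSTANT",
    "escape_probability",
    "alpha_from_selection",
    "escape_count_pmf",
    "sweep_case_probabilities",
    "expected_heterozygosity",
    "volcano_geometry",
    "classic_recovery_distance",
    "selection_bound_from_halfwidth",
    "transformed_spectrum",
    "transformed_class_weights",
    "conditional_sweep",
    "divergence_bound",
]

# Scaled distance beyond the peak at which the excess heterozygosity has
# decayed to 10% of its maximum. Exact for every D > theta: writing
# v = exp(-alpha d) and w = v / v_peak, the 10%-decay condition reduces to
# w^2 - 2 w + 1/10 = 0, whose outer-flank root is w = 1 - 3/sqrt(10).
FLANK_DECAY_CONSTANT = float(np.log(10.0 / (10.0 - 3.0 * np.sqrt(10.0))))


@dataclass(frozen=True)
class SweepParameters:
    """Sweep strength ``alpha`` (per bp) and donor divergence ``D`` (per site)."""

    alpha: float
    D: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")


@dataclass(frozen=True)
class SelectionContext:
    """Biological parameters behind the compound sweep strength.

    r: per-site per-generation recombination rate.
    s: heterozygote selection coefficient of the beneficial allele.
    N: diploid population size of the recipient.
    T_d: donor-recipient split time, units of 4N generations.
    theta: per-site 4N mu.
    """

    r: float
    s: float
    N: float
    T_d: float = 1.0
    theta: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("r", "s", "N", "T_d", "theta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def D(self) -> float:
        return (2.0 * self.T_d + 1.0) * self.theta


@dataclass(frozen=True)
class SweepCaseProbabilities:
    """Pairwise genealogical outcomes during the sweep (star-like).

    P_B: both lineages caught, coalescing on the founding haplotype.
    P_Bb: exactly one lineage escapes by recombination.
    P_bb: both escape.
    P_b: coalescence followed by escape -- zero under the star-like model.
    """

    P_B: float
    P_Bb: float
    P_bb: float
    P_b: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.P_B, self.P_Bb, self.P_bb, self.P_b])


@dataclass(frozen=True)
class VolcanoGeometry:
    """Characteristic scaled distances (alpha*d) and heights of the footprint."""

    theta: float
    D: float
    valley_halfwidth_scaled: float
    peak_position_scaled: float
    peak_height: float
    relative_height: float
    flank_halfwidth_scaled: float
    alpha: float | None = None

    @property
    def valley_halfwidth_bp(self) -> float:
        self._require_alpha()
        return self.valley_halfwidth_scaled / self.alpha

    @property
    def peak_position_bp(self) -> float:
        self._require_alpha()
        return self.peak_position_scaled / self.alpha

    @property
    def flank_halfwidth_bp(self) -> float:
        self._require_alpha()
        return self.flank_halfwidth_scaled / self.alpha

    def _require_alpha(self) -> None:
        if self.alpha is None:
            raise ValueError("base-pair widths require alpha")


def escape_probability(alpha: float, d):
    """``P_e = 1 - exp(-alpha d)``: chance a lineage recombines off the sweep."""
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = -np.expm1(-alpha * d)
    return float(out) if out.ndim == 0 else out


def alpha_from_selection(ctx: SelectionContext) -> float:
    """Compound sweep strength ``alpha = (r/s) ln(2N)`` per base pair."""
    return (ctx.r / ctx.s) * np.log(2.0 * ctx.N)


def _binom_pmf_matrix(n: int, u: np.ndarray) -> np.ndarray:
    """Rows of binomial(n, u[m]) masses, computed from plain powers.

    Direct ``C(n,k) u^k (1-u)^(n-k)`` keeps the n = 2 case bit-consistent
    with the closed-form pairwise heterozygosity.
    """
    import math as _math

    k = np.arange(n + 1)
    comb = np.array([_math.comb(n, int(kk)) for kk in k], dtype=float)
    u = np.asarray(u, dtype=float)[:, None]
    return comb * u**k * (1.0 - u) ** (n - k)


def escape_count_pmf(n: int, alpha: float, d: float) -> np.ndarray:
    """Binomial mass function for the number of escaping lineages, k = 0..n."""
    if n < 2:
        raise ValueError("sample size must be >= 2")
    p = escape_probability(alpha, d)
    return _binom_pmf_matrix(n, np.array([p]))[0]


def sweep_case_probabilities(alpha: float, d: float) -> SweepCaseProbabilities:
    """Pairwise case probabilities; equal to ``escape_count_pmf`` at n = 2."""
    p = escape_probability(alpha, d)
    v = 1.0 - p
    return SweepCaseProbabilities(P_B=v * v, P_Bb=2.0 * p * v, P_bb=p * p)


def expected_heterozygosity(alpha: float, d, theta: float, D: float | None = None,
                            mode: str = "classic"):
    """Expected pairwise diversity at distance ``d`` from the selected site.

    classic:       ``(1 - P_B) theta``           (valley only).
    introgression: ``P_bb theta + P_Bb D``       (valley plus shoulders).
    ``D = theta`` recovers the classic curve, matching a de novo sweep.
    """
    if not theta > 0:
        raise ValueError("theta must be > 0")
    u = np.asarray(escape_probability(alpha, d), dtype=float)  # P_e
    if mode == "classic":
        out = u * (2.0 - u) * theta  # (1 - P_B) theta with P_B = (1-u)^2
    elif mode == "introgression":
        if D is None:
            raise ValueError("introgression mode requires D")
        if D < theta:
            raise ValueError("introgression mode requires D >= theta (D = theta is the classic limit)")
        out = u**2 * theta + (2.0 * u) * (1.0 - u) * D  # P_bb theta + P_Bb D
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(out) if np.ndim(out) == 0 else out


def volcano_geometry(theta: float, D: float, alpha: float | None = None) -> VolcanoGeometry:
    """Closed-form geometry of the heterozygosity volcano (requires ``D > theta``)."""
    if not theta > 0:
        raise ValueError("theta must be > 0")
    if not D > theta:
        raise ValueError("volcano geometry is undefined for D <= theta")
    valley = np.log((2.0 * D - theta) / (2.0 * D - 2.0 * theta))
    peak_pos = np.log((2.0 * D - theta) / (D - theta))
    peak_height = D * D / (2.0 * D - theta)
    return VolcanoGeometry(
        theta=theta,
        D=D,
        valley_halfwidth_scaled=float(valley),
        peak_position_scaled=float(peak_pos),
        peak_height=float(peak_height),
        relative_height=float((peak_height - theta) / theta),
        flank_halfwidth_scaled=float(peak_pos + FLANK_DECAY_CONSTANT),
        alpha=alpha,
    )


def classic_recovery_distance(fraction_recovered: float) -> float:
    """Scaled distance at which a classic sweep valley has recovered a given fraction.

    Solves ``H_classic = fraction * theta``, i.e. ``(1/2) ln(1/(1-fraction))``.
    """
    if not 0 < fraction_recovered < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    return 0.5 * float(np.log(1.0 / (1.0 - fraction_recovered)))


def selection_bound_from_halfwidth(min_halfwidth_bp: float, r: float, N: float,
                                   D_over_theta: float | None = None) -> float:
    """Minimum ``2 N s`` implied by requiring a flank half-width above a bp floor.

    The flank half-width is ``c / alpha`` with ``c`` the scaled 10%-decay
    distance and ``alpha = r ln(2N) / s``; inverting at the floor gives
    ``2 N s >= 2 N r ln(2N) w / c``. By default ``c`` is taken in the
    large-divergence limit ``ln 2 + FLANK_DECAY_CONSTANT``.
    """
    if D_over_theta is None:
        c = float(np.log(2.0)) + FLANK_DECAY_CONSTANT
    else:
        c = volcano_geometry(1.0, D_over_theta).flank_halfwidth_scaled
    return 2.0 * N * r * np.log(2.0 * N) * min_halfwidth_bp / c


# -- the transformed SFS under the sweep --------------------------------------


def divergence_bound(background: UnnormalizedSFS) -> float:
    """Upper bound on fittable ``D``: ``2 D_o`` (polarized) or ``D_o'`` (not)."""
    est = divergence_outgroup(background)
    return 2.0 * est if background.fixed_diffs_polarized else est


def transformed_class_weights(
    background: UnnormalizedSFS,
    params: SweepParameters,
    dists,
    divergence: float | None = None,
    subsamples: np.ndarray | None = None,
    check_bound: bool = True,
) -> np.ndarray:
    """Transformed spectrum ``S'_i`` for a batch of distances, classes 1..n.

    Row ``m`` of the returned ``(len(dists), n)`` array holds
    ``S'_1 .. S'_n`` at ``dists[m]``. For polymorphic classes,

        ``S'_i = sum_{k=i+1}^{n} P_e(k) S_i(k) + P_e(n-i) D/2 + P_e(i) D/2``,

    where ``P_e(k)`` is the binomial escape-count mass and ``S_i(k)`` the
    subsampled background. A fixed difference arises when a mutation hits
    the long branch between the sample MRCA and the species MRCA:

        ``S'_n = (D_o - D/2) sum_{0<k<n} P_e(k) + D_o [P_e(0) + P_e(n)]``.

    The model neglects the within-recipient coalescent time relative to the
    divergence times, so the far-field limit of ``S'_n`` is ``D_o`` rather
    than the background ``S_n``.
    """
    n = background.sample_size
    Do = divergence_outgroup(background) if divergence is None else float(divergence)
    if check_bound and params.D > divergence_bound(background) * (1.0 + 1e-12):
        raise ValueError(
            f"D={params.D} exceeds the divergence bound "
            f"{divergence_bound(background)} for this spectrum"
        )
    M = subsample_matrix(background) if subsamples is None else subsamples
    d = np.atleast_1d(np.asarray(dists, dtype=float))
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    u = -np.expm1(-params.alpha * d)  # escape probability per lineage
    pe = _binom_pmf_matrix(n, u)  # (m, n+1)

    # lower-triangular contraction: first term couples P_e(k) with S_i(k), k > i
    T = np.zeros((n + 1, n + 1))
    for i in range(1, n):
        T[i + 1 :, i] = M[i + 1 :, i]
    first = pe @ T  # (m, n+1); column i holds the k-sum for class i

    out = np.empty((d.size, n))
    half_D = params.D / 2.0
    i_poly = np.arange(1, n)
    out[:, : n - 1] = first[:, 1:n] + half_D * (pe[:, n - i_poly] + pe[:, i_poly])
    interior = pe[:, 1:n].sum(axis=1)
    out[:, n - 1] = (Do - half_D) * interior + Do * (pe[:, 0] + pe[:, n])
    return out


def transformed_spectrum(
    background: UnnormalizedSFS,
    params: SweepParameters,
    d: float,
    divergence: float | None = None,
    subsamples: np.ndarray | None = None,
) -> UnnormalizedSFS:
    """Background spectrum transformed by a sweep at distance ``d`` (bp)."""
    row = transformed_class_weights(background, params, [d], divergence, subsamples)[0]
    weights = np.concatenate([[background.weights[0]], row])
    return UnnormalizedSFS(
        background.sample_size, weights, background.fixed_diffs_polarized,
        require_polymorphic=False,
    )


def conditional_sweep(transformed: UnnormalizedSFS, include_fixed: bool) -> ConditionalSFS:
    """Class probabilities under the sweep (``p'_{i,n}`` or ``q'_{i,n}``).

    Normalization removes the mutation-rate scale, exactly as for the
    background conditionals. In polymorphic-only mode the denominator
    vanishes at ``d = 0`` (all mass sits on the fixed class); the caller
    must guard that case.
    """
    n = transformed.sample_size
    hi = n + 1 if include_fixed else n
    block = transformed.weights[1:hi]
    total = block.sum()
    if total <= 0:
        raise ValueError(
            "sweep conditional undefined: zero weight on the chosen classes "
            "(polymorphic-only mode at d = 0)"
        )
    return ConditionalSFS(n, block / total, include_fixed)
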