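"""Background site-frequency-spectrum algebra.

The scan treats the genome-wide unnormalized site frequency spectrum
``S_i(n)`` (the per-site probability, or raw count, of observing ``i``
derived alleles among ``n`` sampled chromosomes) as the null model.
Everything downstream consumes either hypergeometric subsamples of that
spectrum or the conditional class probabilities given that a site is
informative, so all operations here are scale-free after conditioning.

Classes:
    * ``i = 1 .. n-1`` -- polymorphic sites,
    * ``i = n``        -- fixed differences carried by the recipient lineage
      (or, with unpolarized fixed differences, by either lineage),
    * ``i = 0``        -- mutations private to the outgroup lineage; only
      meaningful when fixed differences are polarized with a second outgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SiteRecord",
    "SiteTable",
    "UnnormalizedSFS",
    "ConditionalSFS",
    "subsample_spectrum",
    "subsample_matrix",
    "theta_pi",
    "theta_L",
    "divergence_outgroup",
    "conditional_background",
]

_PROB_SUM_TOL = 1e-12


@dataclass(frozen=True)
class SiteRecord:
    """One informative site: 1-based position, derived count ``x``, sample size ``n``."""

    position: int
    derived_count: int
    sample_size: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.sample_size < 2:
            raise ValueError(f"sample_size must be >= 2, got {self.sample_size}")
        if not 1 <= self.derived_count <= self.sample_size:
            raise ValueError(
                "informative sites require 1 <= derived_count <= sample_size, "
                f"got x={self.derived_count}, n={self.sample_size}"
            )


class SiteTable:
    """Ordered polarized allele-count records for one chromosome.

    Positions are 1-based, strictly increasing; the sample size is constant
    across the table. Sites with ``x = 0`` (monomorphic ancestral) are never
    stored -- they enter the model only through the unnormalized spectrum.
    """

    def __init__(
        self,
        positions: np.ndarray,
        derived_counts: np.ndarray,
        sample_size: int,
        chromosome_label: str = "chr",
    ) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        derived_counts = np.asarray(derived_counts, dtype=np.int64)
        if positions.ndim != 1 or positions.shape != derived_counts.shape:
            raise ValueError("positions and derived_counts must be 1-D arrays of equal length")
        if positions.size < 1:
            raise ValueError("a site table requires at least one informative site")
        if positions[0] < 1:
            raise ValueError("positions are 1-based; found a position < 1")
        if np.any(np.diff(positions) <= 0):
            bad = int(np.flatnonzero(np.diff(positions) <= 0)[0]) + 1
            raise ValueError(f"positions must be strictly increasing (violated at record {bad + 1})")
        if sample_size < 2:
            raise ValueError("sample_size must be >= 2")
        if np.any(derived_counts < 1) or np.any(derived_counts > sample_size):
            raise ValueError("derived counts must satisfy 1 <= x <= n for every record")
        self.positions = positions
        self.derived_counts = derived_counts
        self.sample_size = int(sample_size)
        self.chromosome_label = chromosome_label

    @classmethod
    def from_records(cls, records: list[SiteRecord], chromosome_label: str = "chr") -> "SiteTable":
        if not records:
            raise ValueError("a site table requires at least one informative site")
        n = records[0].sample_size
        if any(r.sample_size != n for r in records):
            raise ValueError("sample_size must be constant within a table")
        return cls(
            np.array([r.position for r in records]),
            np.array([r.derived_count for r in records]),
            n,
            chromosome_label,
        )

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def records(self) -> list[SiteRecord]:
        return [
            SiteRecord(int(p), int(x), self.sample_size)
            for p, x in zip(self.positions, self.derived_counts)
        ]

    @property
    def span(self) -> tuple[int, int]:
        return int(self.positions[0]), int(self.positions[-1])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SiteTable({self.chromosome_label!r}, L={len(self)}, "
            f"n={self.sample_size}, span={self.span})"
        )


@dataclass
class UnnormalizedSFS:
    """Unnormalized background spectrum ``S_i(n)``, classes ``i = 0..n``.

    Weights may be raw genome-wide counts or per-site probabilities; the
    likelihood machinery only ever uses conditionals, in which the overall
    scale (and hence the mutation rate) cancels.
    """

    sample_size: int
    weights: np.ndarray
    fixed_diffs_polarized: bool = True
    # Background spectra must carry polymorphic weight; spectra transformed
    # by a sweep may concentrate all mass on the fixed class (d = 0 limit).
    require_polymorphic: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.sample_size
        if n < 2:
            raise ValueError("sample_size must be >= 2")
        if self.weights.shape != (n + 1,):
            raise ValueError(
                f"weights must have length n+1 = {n + 1} (classes 0..n), got {self.weights.shape}"
            )
        if np.any(self.weights < 0):
            raise ValueError("spectrum weights must be nonnegative")
        if self.require_polymorphic and self.weights[1:n].sum() <= 0:
            raise ValueError("spectrum must carry positive weight on polymorphic classes 1..n-1")
        if not self.fixed_diffs_polarized and self.weights[0] != 0:
            raise ValueError("S_0 must be 0 when fixed differences are not polarized")

    @property
    def polymorphic_weights(self) -> np.ndarray:
        return self.weights[1 : self.sample_size]

    def scaled(self, factor: float) -> "UnnormalizedSFS":
        return UnnormalizedSFS(self.sample_size, self.weights * factor, self.fixed_diffs_polarized)


@dataclass
class ConditionalSFS:
    """Class probabilities conditional on a site being informative.

    ``include_fixed`` selects between the polymorphic-only conditional
    (classes 1..n-1) and the conditional that also admits recipient-lineage
    fixed differences (classes 1..n).
    """

    sample_size: int
    probabilities: np.ndarray
    include_fixed: bool

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        n = self.sample_size
        expected = n if self.include_fixed else n - 1
        if self.probabilities.shape != (expected,):
            raise ValueError(f"expected {expected} class probabilities, got {self.probabilities.shape}")
        if np.any(self.probabilities < -_PROB_SUM_TOL) or np.any(self.probabilities > 1 + _PROB_SUM_TOL):
            raise ValueError("conditional probabilities must lie in [0, 1]")
        if abs(self.probabilities.sum() - 1.0) > _PROB_SUM_TOL:
            raise ValueError("conditional probabilities must sum to 1 within 1e-12")

    @property
    def classes(self) -> np.ndarray:
        return np.arange(1, self.probabilities.size + 1)

    def for_class(self, i: int) -> float:
        hi = self.sample_size if self.include_fixed else self.sample_size - 1
        if not 1 <= i <= hi:
            raise ValueError(f"class {i} outside the conditional range 1..{hi}")
        return float(self.probabilities[i - 1])


# -- hypergeometric projection ------------------------------------------------

_EXACT_N_MAX = 30  # exact integer binomials below, log-gamma above


def _hypergeom_weights(n: int, k: int) -> np.ndarray:
    """Matrix W[j, i] = C(i, j) C(n-i, k-j) / C(n, k), j = 0..k, i = 0..n."""
    i = np.arange(n + 1)
    j = np.arange(k + 1)
    if n <= _EXACT_N_MAX:
        comb = np.array([[math.comb(a, b) if 0 <= b <= a else 0 for b in range(n + 1)] for a in range(n + 1)], dtype=float)
        num = comb[i[None, :], j[:, None]] * comb[(n - i)[None, :], (k - j[:, None])]
        return num / math.comb(n, k)
    jj, ii = np.meshgrid(j, i, indexing="ij")
    valid = (jj <= ii) & (k - jj <= n - ii) & (k - jj >= 0)
    with np.errstate(invalid="ignore"):
        logw = (
            _log_comb(ii, jj)
            + _log_comb(n - ii, k - jj)
            - _log_comb(np.full_like(ii, n), np.full_like(jj, k))
        )
    w = np.where(valid, np.exp(np.where(valid, logw, 0.0)), 0.0)
    return w


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _subsample_weights(spectrum: UnnormalizedSFS, k: int) -> np.ndarray:
    """Classes 0..k of the spectrum projected onto k lineages (k >= 1)."""
    n = spectrum.sample_size
    w = _hypergeom_weights(n, k)  # (k+1, n+1)
    out = w @ spectrum.weights
    out[0] = spectrum.weights[0]  # outgroup-private class is untouched by subsampling
    return out


def subsample_spectrum(spectrum: UnnormalizedSFS, k: int) -> UnnormalizedSFS:
    """Project the spectrum onto a subsample of ``k`` lineages.

    ``S_j(k) = sum_{i=j}^{n} S_i(n) C(i,j) C(n-i,k-j) / C(n,k)`` for
    ``j = 1..k``; the input scale is preserved and ``k = n`` is the identity.
    """
    if not 2 <= k <= spectrum.sample_size:
        raise ValueError(f"subsample size must satisfy 2 <= k <= n, got k={k}, n={spectrum.sample_size}")
    return UnnormalizedSFS(k, _subsample_weights(spectrum, k), spectrum.fixed_diffs_polarized)


def subsample_matrix(spectrum: UnnormalizedSFS) -> np.ndarray:
    """All subsampled spectra at once: ``M[k, j] = S_j(k)`` for ``1 <= j <= k <= n``.

    Precomputed once per dataset; the sweep-transformed spectrum consumes
    rows of this matrix millions of times during a scan.
    """
    n = spectrum.sample_size
    M = np.zeros((n + 1, n + 1))
    for k in range(1, n + 1):
        M[k, : k + 1] = _subsample_weights(spectrum, k)
        M[k, 0] = 0.0
    return M


def theta_pi(spectrum: UnnormalizedSFS) -> float:
    """Pairwise-difference estimator of per-site diversity: ``S_1(2)``."""
    return float(_subsample_weights(spectrum, 2)[1])


def theta_L(spectrum: UnnormalizedSFS) -> float:
    """Derived-count-weighted estimator: ``(1/(n-1)) sum_{i<n} i S_i(n)``."""
    n = spectrum.sample_size
    i = np.arange(1, n)
    return float((i * spectrum.weights[1:n]).sum() / (n - 1))


def divergence_outgroup(spectrum: UnnormalizedSFS) -> float:
    """Expected recipient-to-ancestor divergence ``D_o = S_n + (1/n) sum_{i<n} i S_i``.

    Equals the class-1 weight of the spectrum projected onto a single
    lineage. With unpolarized fixed differences the same expression
    estimates the full recipient-outgroup divergence ``D_o'``.
    """
    n = spectrum.sample_size
    i = np.arange(1, n)
    return float(spectrum.weights[n] + (i * spectrum.weights[1:n]).sum() / n)


def conditional_background(spectrum: UnnormalizedSFS, include_fixed: bool) -> ConditionalSFS:
    """Class probabilities given the site is informative (``p_{i,n}`` or ``q_{i,n}``)."""
    n = spectrum.sample_size
    hi = n + 1 if include_fixed else n
    block = spectrum.weights[1:hi]
    total = block.sum()
    if total <= 0:
        raise ValueError("conditional spectrum undefined: zero total weight on the chosen classes")
    return ConditionalSFS(n, block / total, include_fixed)
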