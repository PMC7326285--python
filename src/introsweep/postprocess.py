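"""Post-scan curation and evaluation.

Peak calling on the scan profile, the candidate filters used to separate
genuine volcano footprints from artifacts (divergence above diversity,
minimum volcano half-width, data-desert exclusion), the
polymorphism-to-divergence diagnostics applied to candidate regions
(one-tailed binomial against the genomic background; a
Hudson-Kreitman-Aguade-style 2x2 contingency comparison of shoulders
against the central valley), and the top-k detection-probability summary
used in power experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .scan import ScanResult
from .sfs import SiteTable
from .sweep import volcano_geometry

__all__ = [
    "CandidatePeak",
    "PolyDivCounts",
    "PolyDivDiagnostics",
    "call_peaks",
    "filter_candidates",
    "poly_div_diagnostics",
    "detection_probability",
]


@dataclass
class CandidatePeak:
    """A curated scan outlier with its inferred volcano geometry."""

    position: int
    lnCLR: float
    alpha_hat: float
    D_hat: float
    valley_halfwidth_bp: float = float("nan")
    flank_halfwidth_bp: float = float("nan")
    filter_flags: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.filter_flags.values()) if self.filter_flags else True


@dataclass(frozen=True)
class PolyDivCounts:
    """Polymorphic and fixed-difference counts within one region."""

    polymorphic: int
    fixed: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.polymorphic < 0 or self.fixed < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.polymorphic + self.fixed


@dataclass(frozen=True)
class PolyDivDiagnostics:
    """p-values of the shoulder polymorphism:divergence diagnostics."""

    binomial_p: float | None
    hka_p: float | None
    hka_method: str | None
    notes: tuple[str, ...] = ()


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus collapse to their midpoint."""
    v = np.asarray(values, dtype=float)
    if v.size == 1:
        return np.array([0])
    out = []
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == v.size - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            out.append((i + j) // 2)
        i = j + 1
    return np.asarray(out, dtype=int)


def call_peaks(
    scan_result: ScanResult,
    min_lnCLR: float = 20.0,
    min_separation: float = 15_000.0,
) -> list[CandidatePeak]:
    """Local maxima of lnCLR above threshold, thinned greedily.

    Within any window of ``min_separation`` base pairs (center to center)
    only the highest-scoring peak survives; ties retain the earlier
    position.
    """
    frame = scan_result.frame
    if len(frame) == 0:
        raise ValueError("empty scan result")
    lnclr = frame["lnCLR"].to_numpy()
    pos = frame["location"].to_numpy()
    idx = _local_maxima(lnclr)
    idx = idx[lnclr[idx] >= min_lnCLR]
    order = idx[np.lexsort((pos[idx], -lnclr[idx]))]
    kept: list[int] = []
    for i in order:
        if all(abs(pos[i] - pos[k]) >= min_separation for k in kept):
            kept.append(i)
    kept.sort(key=lambda i: pos[i])
    theta = scan_result.metadata.get("theta_pi")
    peaks = []
    for i in kept:
        peak = CandidatePeak(
            position=int(pos[i]),
            lnCLR=float(lnclr[i]),
            alpha_hat=float(frame["alpha"].iloc[i]),
            D_hat=float(frame["D"].iloc[i]),
        )
        if theta is not None and peak.D_hat > theta:
            geom = volcano_geometry(theta, peak.D_hat, alpha=peak.alpha_hat)
            peak.valley_halfwidth_bp = geom.valley_halfwidth_bp
            peak.flank_halfwidth_bp = geom.flank_halfwidth_bp
        peaks.append(peak)
    return peaks


def filter_candidates(
    peaks: list[CandidatePeak],
    scan_metadata: dict,
    site_table: SiteTable,
    gap_quantile: float = 0.9995,
    min_halfwidth_bp: float = 5_000.0,
) -> list[CandidatePeak]:
    """Apply the candidate filters; annotate every peak, return the survivors.

    Filters (all must pass):
      * ``divergence_above_diversity``: D_hat strictly above theta_pi;
      * ``halfwidth``: inferred flank half-width above ``min_halfwidth_bp``;
      * ``site_gap``: distance to the nearest informative site below the
        ``gap_quantile`` of the chromosome's inter-site-gap distribution
        (peaks inside data deserts are artifacts).
    """
    theta = scan_metadata["theta_pi"]
    gaps = np.diff(site_table.positions)
    gap_threshold = float(np.quantile(gaps, gap_quantile)) if gaps.size else np.inf
    retained = []
    for peak in peaks:
        nearest = float(np.min(np.abs(site_table.positions - peak.position)))
        flags = {
            "divergence_above_diversity": peak.D_hat > theta,
            "halfwidth": bool(np.isfinite(peak.flank_halfwidth_bp))
            and peak.flank_halfwidth_bp > min_halfwidth_bp,
            "site_gap": nearest < gap_threshold,
        }
        peak.filter_flags = flags
        if all(flags.values()):
            retained.append(peak)
    return retained


def poly_div_diagnostics(
    shoulders: PolyDivCounts,
    valley: PolyDivCounts | None = None,
    background_poly_fraction: float | None = None,
) -> PolyDivDiagnostics:
    """Polymorphism:divergence diagnostics for a candidate volcano.

    One-tailed binomial test of the shoulder polymorphic fraction
    exceeding the genome-wide background fraction, and a 2x2 HKA-style
    contingency comparison of the shoulders against the central valley:
    chi-square when all expected counts reach 5, otherwise Fisher's exact
    test, one-tailed in the direction of shoulder polymorphism excess.
    """
    notes: list[str] = []
    binom_p: float | None = None
    if background_poly_fraction is not None:
        if shoulders.total == 0:
            notes.append("shoulders contain no informative sites; binomial test undefined")
        else:
            binom_p = stats.binomtest(
                shoulders.polymorphic, shoulders.total,
                background_poly_fraction, alternative="greater",
            ).pvalue
    hka_p: float | None = None
    hka_method: str | None = None
    if valley is not None:
        if valley.total == 0 or shoulders.total == 0:
            notes.append("a region holds no informative sites; HKA comparison undefined")
        else:
            table = np.array(
                [[shoulders.polymorphic, shoulders.fixed], [valley.polymorphic, valley.fixed]]
            )
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            if np.all(expected >= 5):
                chi2 = stats.chi2_contingency(table, correction=False).statistic
                direction = shoulders.polymorphic * valley.fixed >= valley.polymorphic * shoulders.fixed
                p_two = stats.chi2.sf(chi2, df=1)
                hka_p = p_two / 2.0 if direction else 1.0 - p_two / 2.0
                hka_method = "chi2"
            else:
                hka_p = stats.fisher_exact(table, alternative="greater")[1]
                hka_method = "fisher"
    return PolyDivDiagnostics(binom_p, hka_p, hka_method, tuple(notes))


def detection_probability(
    sweep_scans: list[ScanResult],
    neutral_scans: list[ScanResult],
    top_k: int,
    peak_merge_window: int = 10,
) -> np.ndarray:
    """Probability the sweep outranks the top-k neutral background peaks.

    Builds the neutral peak pool as the local maxima of each neutral scan's
    LR sequence, merging maxima closer than ``peak_merge_window`` test-site
    indices (the higher survives); then, for each ``k`` in 1..top_k,
    reports the fraction of sweep scans whose maximum LR strictly exceeds
    the k-th largest pooled neutral peak. The statistic uses only each
    sweep scan's maximum, so true sweep positions are not consulted.
    Non-decreasing in ``k`` and invariant to monotone transforms of LR.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    pool: list[float] = []
    for res in neutral_scans:
        lr = res.frame["LR"].to_numpy()
        idx = _local_maxima(lr)
        merged: list[int] = []
        for i in idx:
            if merged and i - merged[-1] < peak_merge_window:
                if lr[i] > lr[merged[-1]]:
                    merged[-1] = i
            else:
                merged.append(i)
        pool.extend(lr[merged])
    if len(pool) < top_k:
        raise ValueError(f"only {len(pool)} neutral peaks available for top_k={top_k}")
    thresholds = np.sort(np.asarray(pool))[::-1][:top_k]
    sweep_max = np.array([res.frame["LR"].max() for res in sweep_scans])
    return np.array([(sweep_max > thresholds[k - 1]).mean() for k in range(1, top_k + 1)])
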