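"""Model-faithful synthetic site tables.

The generator draws data from exactly the probabilistic model the scan
fits: every base pair is independently informative with probability equal
to the total background spectrum weight, and an informative site's class
is drawn from the background conditional -- or, within the scaled-distance
footprint of a planted sweep, from the sweep-transformed conditional at
its distance from the selected site. Sites are independent (no linkage
disequilibrium), matching the composite-likelihood independence
assumption, so recovery experiments on these tables are exact model-match
tests rather than tests of robustness to coalescent correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sfs import SiteTable, UnnormalizedSFS, divergence_outgroup, subsample_matrix
from .sweep import SweepParameters, divergence_bound, transformed_class_weights

__all__ = ["SimulationSpec", "neutral_spectrum", "simulate_sites", "simulate_replicates"]

# Defaults mirror the study conditions of the pairwise-diversity and power
# analyses: theta = 0.002 (N = 5000, mu = 1e-7), n = 40 chromosomes, and a
# human-like recipient-to-ancestor divergence of 0.0125 per site.
_DEFAULT_THETA = 0.002
_DEFAULT_DO = 0.0125
_DEFAULT_N = 40

_AD_FOOTPRINT = 12.0  # beyond this scaled distance the sweep law is background


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one synthetic chromosome.

    planted_sweep: optional ``(position, SweepParameters)``; when present,
    informative sites within the sweep footprint draw their class from the
    transformed conditional at their distance from the planted position.
    """

    region_length: int
    sample_size: int = _DEFAULT_N
    theta: float = _DEFAULT_THETA
    D_o: float = _DEFAULT_DO
    planted_sweep: tuple[int, SweepParameters] | None = None
    seed: int | None = None
    fixed_diffs_polarized: bool = True

    def __post_init__(self) -> None:
        if self.region_length < 1:
            raise ValueError("region_length must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is mandatory: synthetic tables must be reproducible")
        if self.planted_sweep is not None:
            pos = self.planted_sweep[0]
            if not 1 <= pos <= self.region_length:
                raise ValueError("planted sweep position must lie within the region")


def neutral_spectrum(n: int, theta: float, D_o: float,
                     fixed_diffs_polarized: bool = True) -> UnnormalizedSFS:
    """Standard-neutrality background as per-site probabilities.

    ``S_i = theta / i`` for polymorphic classes and
    ``S_n = D_o - (n-1) theta / n`` so that the divergence estimator
    returns ``D_o`` exactly.
    """
    if n < 2:
        raise ValueError("sample size must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    s_n = D_o - (n - 1) * theta / n
    if s_n < 0:
        raise ValueError(f"D_o must be >= (n-1) theta / n = {(n - 1) * theta / n:.6g}")
    weights = np.zeros(n + 1)
    weights[1:n] = theta / np.arange(1, n)
    weights[n] = s_n
    return UnnormalizedSFS(n, weights, fixed_diffs_polarized)


def simulate_sites(spec: SimulationSpec, background: UnnormalizedSFS | None = None) -> SiteTable:
    """Draw one synthetic site table under the spec's conditions.

    The background spectrum weights are interpreted as per-site
    probabilities; their sum over classes 1..n is the informative-site
    density, held at the background value across the whole region.
    """
    if background is None:
        background = neutral_spectrum(
            spec.sample_size, spec.theta, spec.D_o, spec.fixed_diffs_polarized
        )
    n = background.sample_size
    p_classes = background.weights[1:]
    p_total = float(p_classes.sum())
    if p_total > 1.0:
        raise ValueError(
            f"total per-site informative probability {p_total:.4g} exceeds 1; "
            "the spectrum does not look like per-site probabilities"
        )
    rng = np.random.default_rng(spec.seed)
    hit = rng.random(spec.region_length) < p_total
    positions = np.flatnonzero(hit) + 1  # 1-based
    if positions.size == 0:
        raise ValueError("no informative sites drawn; enlarge the region or the spectrum")

    q = p_classes / p_total
    counts = rng.choice(np.arange(1, n + 1), size=positions.size, p=q)

    if spec.planted_sweep is not None:
        sweep_pos, params = spec.planted_sweep
        if params.D > divergence_bound(background) * (1 + 1e-12):
            raise ValueError("planted D exceeds the divergence bound of the background")
        d = np.abs(positions.astype(float) - sweep_pos)
        d = np.maximum(d, 1.0)
        near = params.alpha * d <= _AD_FOOTPRINT
        if np.any(near):
            weights = transformed_class_weights(
                background, params, d[near],
                divergence=divergence_outgroup(background),
                subsamples=subsample_matrix(background),
            )
            probs = weights / weights.sum(axis=1, keepdims=True)
            u = rng.random(probs.shape[0])
            counts[near] = 1 + (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    label = f"sim_seed{spec.seed}"
    return SiteTable(positions, counts, n, chromosome_label=label)


def simulate_replicates(
    spec: SimulationSpec,
    n_replicates: int,
    base_seed: int | None = None,
    background: UnnormalizedSFS | None = None,
) -> list[SiteTable]:
    """Independent tables seeded ``base_seed + j`` for ``j = 0..n_replicates-1``."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if base_seed is None:
        base_seed = spec.seed
    return [
        simulate_sites(replace(spec, seed=base_seed + j), background)
        for j in range(n_replicates)
    ]
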