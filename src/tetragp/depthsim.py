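"""Sequencing-depth downsampling of an observed read-count matrix.

Lower-depth scenarios are simulated per datapoint: the new total read count
is drawn from Poisson(target depth) conditioned on the minimum depth (2 by
default), and the new alternative-read count from Binomial(new total,
observed ratio).  Marker positions are untouched — only depths change, so a
scenario shares its marker panel with the benchmark data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ReadCountMatrix, child_seed, sample_truncated_poisson

__all__ = ["DepthScenario", "downsample", "replicate_downsample"]

#: depth levels examined in the study (plus the 60X benchmark)
DEFAULT_DEPTH_TARGETS = (2.0, 6.0, 12.0, 24.0, 48.0)


@dataclass(frozen=True)
class DepthScenario:
    target_mean_depth: float
    min_depth: int = 2
    replicate_index: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.target_mean_depth <= 0:
            raise ValueError("target_mean_depth must be positive")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")


def downsample(
    rc: ReadCountMatrix, scenario: DepthScenario, mode: str = "binomial"
) -> ReadCountMatrix:
    """Downsample every datapoint to the scenario's depth.

    mode='binomial' (default): new totals are drawn fresh from the truncated
    Poisson and split Binomial(n', p) with p the observed input ratio — the
    resampling model consistent with the ratio parameterization.
    mode='hypergeometric': subsample n' reads without replacement from the
    observed reads (requires n' <= observed depth; excess totals are capped),
    available for sensitivity checks.
    """
    if mode not in ("binomial", "hypergeometric"):
        raise ValueError("mode must be 'binomial' or 'hypergeometric'")
    depth_in = rc.depth
    if np.any((~rc.missing) & (depth_in == 0)):
        raise ValueError("input contains zero-depth datapoints")
    rng = np.random.default_rng(scenario.seed)
    new_n = sample_truncated_poisson(
        rng, scenario.target_mean_depth, scenario.min_depth, rc.ao.shape
    )
    if mode == "binomial":
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(depth_in > 0, rc.ao / np.maximum(depth_in, 1), 0.0)
        ao = rng.binomial(new_n, p)
    else:
        n_draw = np.minimum(new_n, depth_in)
        # pad empty (missing) cells so the sampler's preconditions hold; their
        # draws are zeroed immediately below
        ro_pad = np.where(depth_in > 0, rc.ro, 1)
        ao = rng.hypergeometric(rc.ao, ro_pad, np.maximum(n_draw, 1))
        ao = np.where(n_draw > 0, ao, 0)
        new_n = n_draw
    ao = np.where(rc.missing, 0, ao)
    new_n = np.where(rc.missing, 0, new_n)
    return ReadCountMatrix(
        ao, new_n - ao, rc.individual_ids, rc.marker_ids, rc.missing.copy()
    )


def replicate_downsample(
    rc: ReadCountMatrix,
    targets,
    n_reps: int = 5,
    master_seed: int = 0,
    min_depth: int = 2,
    mode: str = "binomial",
) -> dict:
    """Independent replicate downsamplings per target depth.

    Returns {target: [ReadCountMatrix, ...]} with deterministic per-replicate
    seeds derived from (master seed, target index, replicate index).
    """
    targets = list(targets)
    if not targets:
        raise ValueError("targets must be non-empty")
    out: dict = {}
    for t_idx, target in enumerate(targets):
        reps = []
        for r in range(n_reps):
            sc = DepthScenario(
                target_mean_depth=float(target),
                min_depth=min_depth,
                replicate_index=r,
                seed=child_seed(master_seed, t_idx, r),
            )
            reps.append(downsample(rc, sc, mode=mode))
        out[target] = reps
    return out
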