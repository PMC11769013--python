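"""Synthetic reference and patient populations.

The generator emulates the statistical structure of the packaged
reference grid and nothing more: each parameter's normalised values are
drawn through a monotone piecewise-linear quantile function interpolating
the eleven tabulated anchors (an inverse-CDF sampler, not a parametric
family — the anchors are all the distributional information available).

Healthy animals sample the HEALTHY quantile function directly.  Cardiac
animals sample a deconvolved component chosen so that the *pooled*
population reproduces the TOTAL anchors: with healthy fraction ``q``,
``F_cardiac = (F_total - q * F_healthy) / (1 - q)``, evaluated on a dense
grid and forced monotone where the subtraction locally dips (duplicated
healthy anchors create density spikes the total table cannot absorb).
The calibration residuals of that correction are computable via
:func:`pooled_quantile_residuals` rather than hidden.

By default draws are Latin-hypercube stratified (one uniform per 1/n
stratum, randomly permuted): each value is still marginally a draw from
the target distribution, but a size-n population represents the target
quantiles with O(1/n) error instead of O(1/sqrt(n)).  Pass
``sampling="iid"`` for independent uniforms.

Raw centimetre values are back-computed as ``normalised * weight**b`` with
body weights uniform on the configured range, so re-normalising a
generated population reproduces the sampled normalised values exactly.
Parameters are drawn independently: the reference grid carries no
covariance information, and none is invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError, InvalidSummaryError
from .normalization import AllometricExponents, MeasurementRecord, NormalizedProfile
from .params import DISPLAY_ORDER, Group, Parameter, Population
from .reference import PercentileSummary, ReferenceTable

#: Default group sizes: the study population the reference grid came from.
DEFAULT_N_HEALTHY = 802
DEFAULT_N_CARDIAC = 2165
#: Default body-weight range (kg): small-breed dogs, the validated demographic.
DEFAULT_WEIGHT_RANGE = (2.0, 20.0)

_GRID_POINTS = 4097


class PiecewiseLinearQuantile:
    """Monotone piecewise-linear quantile function u in [0,1] -> value."""

    def __init__(self, probs: Sequence[float], values: Sequence[float], name: str = "") -> None:
        self.probs = np.asarray(probs, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.name = name
        if np.any(np.diff(self.probs) <= 0):
            raise InvalidSummaryError(f"{name}: probabilities must strictly increase")
        if np.any(np.diff(self.values) < 0):
            raise InvalidSummaryError(f"{name}: anchor values must be non-decreasing")

    def __call__(self, u):
        arr = np.asarray(u, dtype=float)
        if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
            raise InvalidInputError(f"{self.name}: u must lie in [0, 1]")
        out = np.interp(arr, self.probs, self.values)
        return float(out) if np.isscalar(u) else out


def quantile_function_from_summary(summary: PercentileSummary) -> PiecewiseLinearQuantile:
    """Inverse CDF through the eleven anchors; exact at every anchor."""
    from .reference import ANCHOR_PROBS

    return PiecewiseLinearQuantile(
        ANCHOR_PROBS,
        summary.anchors,
        name=f"{summary.parameter.value}/{summary.population.value}",
    )


def _cdf_on_grid(summary: PercentileSummary, grid: np.ndarray) -> np.ndarray:
    """Piecewise-linear CDF; duplicated anchor values become jumps."""
    from .reference import ANCHOR_PROBS

    xs: list[float] = []
    ps: list[float] = []
    for v, p in zip(summary.anchors, ANCHOR_PROBS):
        # tied anchors are a jump in the CDF; step just above the tied value
        x = xs[-1] + 1e-9 if xs and v <= xs[-1] else float(v)
        xs.append(x)
        ps.append(float(p))
    return np.interp(grid, xs, ps, left=0.0, right=1.0)


def _cardiac_cdf_grid(
    healthy: PercentileSummary, total: PercentileSummary, healthy_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    if not 0.0 <= healthy_fraction < 1.0:
        raise InvalidInputError(f"healthy_fraction must be in [0, 1), got {healthy_fraction}")
    anchors = np.r_[healthy.anchors, total.anchors]
    grid = np.union1d(
        np.linspace(total.minimum, total.maximum, _GRID_POINTS),
        anchors[(anchors >= total.minimum) & (anchors <= total.maximum)],
    )
    f_t = _cdf_on_grid(total, grid)
    f_h = _cdf_on_grid(healthy, grid)
    q = healthy_fraction
    f_c = (f_t - q * f_h) / (1.0 - q)
    f_c = np.maximum.accumulate(np.clip(f_c, 0.0, 1.0))
    f_c[0], f_c[-1] = 0.0, 1.0
    return grid, f_c


def cardiac_quantile_function(
    healthy: PercentileSummary, total: PercentileSummary, healthy_fraction: float
) -> PiecewiseLinearQuantile:
    """Quantile function of the cardiac component of the pooled mixture."""
    grid, f_c = _cardiac_cdf_grid(healthy, total, healthy_fraction)
    # collapse flat CDF runs so probs strictly increase
    keep = np.r_[True, f_c[1:] > f_c[:-1]]
    return PiecewiseLinearQuantile(
        f_c[keep], grid[keep], name=f"{total.parameter.value}/CARDIAC(q={healthy_fraction:.4f})"
    )


def pooled_quantile_residuals(
    healthy: PercentileSummary, total: PercentileSummary, healthy_fraction: float
) -> dict[float, float]:
    """Anchor-wise error of the calibrated mixture against the TOTAL targets.

    Returns {probability: pooled quantile - target anchor}; nonzero entries
    come from the monotone correction of the deconvolved cardiac CDF.
    """
    from .reference import ANCHOR_PROBS

    grid, f_c = _cardiac_cdf_grid(healthy, total, healthy_fraction)
    pooled = healthy_fraction * _cdf_on_grid(healthy, grid) + (1.0 - healthy_fraction) * f_c
    keep = np.r_[True, pooled[1:] > pooled[:-1]]
    pooled_q = np.interp(ANCHOR_PROBS, pooled[keep], grid[keep])
    return {
        p: float(pooled_q[i] - total.anchors[i]) for i, p in enumerate(ANCHOR_PROBS)
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated population.

    Defaults mirror the reference study: 802 healthy and 2165 cardiac
    dogs weighing 2-20 kg.  ``reference`` supplies the target quantiles;
    ``exponents`` the allometric constants used to back-compute raw cm.
    """

    reference: ReferenceTable
    exponents: AllometricExponents
    n_healthy: int = DEFAULT_N_HEALTHY
    n_cardiac: int = DEFAULT_N_CARDIAC
    seed: int = 0
    weight_range: tuple[float, float] = DEFAULT_WEIGHT_RANGE
    parameters: tuple[Parameter, ...] = DISPLAY_ORDER
    sampling: str = "stratified"

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_cardiac < 0:
            raise InvalidInputError("group sizes must be non-negative")
        lo, hi = self.weight_range
        if not (0 < lo < hi):
            raise InvalidInputError(f"weight_range must satisfy 0 < min < max, got {self.weight_range}")
        if self.sampling not in ("stratified", "iid"):
            raise InvalidInputError(f"sampling must be 'stratified' or 'iid', got {self.sampling!r}")


def _draw_u(rng: np.random.Generator, n: int, sampling: str) -> np.ndarray:
    if sampling == "iid":
        return rng.random(n)
    return (rng.permutation(n) + rng.random(n)) / n


def generate_population(
    config: SyntheticConfig, with_normalized: bool = False
) -> list[MeasurementRecord] | tuple[list[MeasurementRecord], list[NormalizedProfile]]:
    """Draw the configured population; fully reproducible from the seed.

    With ``with_normalized=True`` also returns the sampled normalised
    profiles (useful for consistency checks).
    """
    params = config.parameters
    n_total = config.n_healthy + config.n_cardiac
    q = config.n_healthy / n_total if n_total else 0.0

    def summaries(pop: Population) -> dict[Parameter, PercentileSummary]:
        out = {}
        for p in params:
            try:
                out[p] = config.reference.summary(p, pop)
            except KeyError as exc:
                raise ConfigurationError(str(exc)) from exc
        return out

    group_qfs: dict[Group, dict[Parameter, PiecewiseLinearQuantile]] = {}
    if config.n_healthy:
        group_qfs[Group.HEALTHY] = {
            p: quantile_function_from_summary(s) for p, s in summaries(Population.HEALTHY).items()
        }
    if config.n_cardiac:
        healthy_s = summaries(Population.HEALTHY)
        total_s = summaries(Population.TOTAL)
        group_qfs[Group.CARDIAC] = {
            p: cardiac_quantile_function(healthy_s[p], total_s[p], q) for p in params
        }

    rng = np.random.default_rng(config.seed)
    lo, hi = config.weight_range
    records: list[MeasurementRecord] = []
    profiles: list[NormalizedProfile] = []
    plan = ((Group.HEALTHY, config.n_healthy, "H"), (Group.CARDIAC, config.n_cardiac, "C"))
    for group, n, prefix in plan:
        if n == 0:
            continue
        weights = rng.uniform(lo, hi, n)
        normalized = {
            p: group_qfs[group][p](_draw_u(rng, n, config.sampling)) for p in params
        }
        for i in range(n):
            w = float(weights[i])
            normed_i = {p: float(normalized[p][i]) for p in params}
            raw_i = {p: normed_i[p] * w ** config.exponents[p] for p in params}
            subject = f"{prefix}{i + 1:05d}"
            records.append(MeasurementRecord(subject, w, group, raw_i))
            if with_normalized:
                profiles.append(NormalizedProfile(subject, normed_i))
    if with_normalized:
        return records, profiles
    return records
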