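"""Smooth 1D Gaussian random fields, example-data generators and
continuum power analysis.

Smooth fields are white Gaussian noise convolved with a Gaussian kernel of
a given FWHM (node units), rescaled so that every node has unit variance in
expectation -- including the field ends, where the truncated kernel is
renormalised.  The generators build the standard study conditions of this
kind of analysis: a two-group set with Gaussian-pulse "bursts" at two
nodes, and a paired gait-like set of periodic knee-flexion curves with a
localised left-right asymmetry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

from .data import TrajectorySet
from .rft import spm_t_test

__all__ = [
    "FieldSpec",
    "ContinuumModel",
    "PowerCurve",
    "gaussian_pulse",
    "smooth_gaussian_fields",
    "make_two_local_max",
    "make_gait_like",
    "continuum_power",
]

_FWHM_TO_SD = 1.0 / math.sqrt(8.0 * math.log(2.0))


@dataclass(frozen=True)
class FieldSpec:
    """Specification of a set of smooth unit-variance Gaussian fields."""

    J: int
    Q: int = 101
    fwhm: float = 10.0
    amplitude_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.J < 2:
            raise ValueError(f"need J >= 2 trials, got {self.J}")
        if self.Q < 3:
            raise ValueError(f"need Q >= 3 nodes, got {self.Q}")
        if not self.fwhm > 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")


def gaussian_pulse(q: int, center: float, fwhm: float,
                   amplitude: float = 1.0) -> np.ndarray:
    """A Gaussian bump over the node axis (``center`` in 0-based nodes)."""
    x = np.arange(q, dtype=float)
    sd = fwhm * _FWHM_TO_SD
    return amplitude * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _smooth_unit_fields(rng: np.random.Generator, j: int, q: int,
                        fwhm: float) -> np.ndarray:
    """J x Q smooth Gaussian fields with exactly unit pointwise variance."""
    sd = max(fwhm * _FWHM_TO_SD, 1e-12)
    half = max(int(math.ceil(4.0 * sd)), 1)
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sd) ** 2)
    white = rng.standard_normal((j, q))
    smoothed = convolve1d(white, kernel, axis=1, mode="constant", cval=0.0)
    # per-node variance of the (edge-truncated) convolution
    var = convolve1d(np.ones(q), kernel ** 2, mode="constant", cval=0.0)
    return smoothed / np.sqrt(var)


def smooth_gaussian_fields(spec: FieldSpec, label: str = "smooth-fields") -> TrajectorySet:
    """Generate smooth unit-variance Gaussian trajectories.

    Reproducible under a fixed ``spec.seed``.  A FWHM of the order of the
    field length produces near-constant trajectories (warned).
    """
    if spec.fwhm >= spec.Q:
        warnings.warn(
            f"fwhm {spec.fwhm} >= field length {spec.Q}: fields are "
            "near-constant",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    values = spec.amplitude_sd * _smooth_unit_fields(rng, spec.J, spec.Q, spec.fwhm)
    return TrajectorySet(values=values, label=label)


def make_two_local_max(n_per_group: int = 6, q: int = 101,
                       burst_nodes: tuple[float, float] = (25, 75),
                       burst_amplitude: float = 3.0,
                       burst_fwhm: float = 10.0,
                       noise_fwhm: float = 10.0,
                       seed: int | None = None) -> tuple[TrajectorySet, TrajectorySet]:
    """Two-group set: smooth unit Gaussian trajectories, the second group
    with Gaussian-pulse mean offsets ("bursts") at two nodes.

    Defaults (2 x n = 6 trials, Q = 101, bursts at nodes 25 and 75) follow
    the canonical two-local-maximum demonstration design; the burst
    amplitude 3.0 (in units of the trajectory SD) and width 10 nodes make
    clusters near both bursts detectable by a classical SPM in a majority
    of random draws at this sample size.
    """
    for node in burst_nodes:
        if not 0 <= node <= q - 1:
            raise ValueError(f"burst node {node} outside field 0..{q - 1}")
    rng = np.random.default_rng(seed)
    g1 = _smooth_unit_fields(rng, n_per_group, q, noise_fwhm)
    g2 = _smooth_unit_fields(rng, n_per_group, q, noise_fwhm)
    effect = sum(gaussian_pulse(q, node, burst_fwhm, burst_amplitude)
                 for node in burst_nodes)
    return (TrajectorySet(values=g1, label="group-1"),
            TrajectorySet(values=g2 + effect, label="group-2"))


def gait_baseline(q: int = 101) -> np.ndarray:
    """Knee-flexion-like baseline (degrees): small stance-phase flexion
    bump and a large swing-phase flexion peak."""
    return (5.0
            + 15.0 * gaussian_pulse(q, 0.15 * (q - 1), 0.22 * (q - 1))
            + 60.0 * gaussian_pulse(q, 0.72 * (q - 1), 0.20 * (q - 1)))


def make_gait_like(n_cycles: int, asymmetry_deg: float = 0.0,
                   within_sd: float = 2.4, q: int = 101,
                   noise_fwhm: float = 20.0,
                   asymmetry_center: float = 76.0,
                   asymmetry_fwhm: float = 12.0,
                   seed: int | None = None) -> tuple[TrajectorySet, TrajectorySet]:
    """Paired gait-like set: left/right knee flexion curves over many
    cycles, with an optional localised asymmetry.

    Both legs share a smooth periodic baseline; the second leg is offset
    by a Gaussian pulse of peak height ``asymmetry_deg`` (degrees) late in
    the cycle.  Cycle-to-cycle noise is a smooth unit field scaled by
    ``within_sd`` (default 2.4 deg, a typical within-subject kinematic
    variability).
    """
    if n_cycles < 2:
        raise ValueError(f"need at least 2 cycles, got {n_cycles}")
    rng = np.random.default_rng(seed)
    base = gait_baseline(q)
    asym = gaussian_pulse(q, asymmetry_center, asymmetry_fwhm, asymmetry_deg)
    left = base + within_sd * _smooth_unit_fields(rng, n_cycles, q, noise_fwhm)
    right = (base + asym
             + within_sd * _smooth_unit_fields(rng, n_cycles, q, noise_fwhm))
    return (TrajectorySet(values=left, label="left"),
            TrajectorySet(values=right, label="right"))


@dataclass(frozen=True)
class ContinuumModel:
    """A continuum data-generating model: baseline + effect + smooth noise.

    ``baseline`` and ``effect`` are length-Q curves in the units of the
    variable; ``noise`` specifies the smooth random component (its
    ``amplitude_sd`` is the trial-to-trial SD)."""

    baseline: np.ndarray
    effect: np.ndarray
    noise: FieldSpec

    def __post_init__(self):
        baseline = np.asarray(self.baseline, dtype=float)
        effect = np.asarray(self.effect, dtype=float)
        if baseline.shape != (self.noise.Q,) or effect.shape != (self.noise.Q,):
            raise ValueError("baseline and effect must be length-Q arrays")
        object.__setattr__(self, "baseline", baseline)
        object.__setattr__(self, "effect", effect)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        noise = self.noise.amplitude_sd * _smooth_unit_fields(
            rng, n, self.noise.Q, self.noise.fwhm)
        return self.baseline + self.effect + noise


@dataclass(frozen=True)
class PowerCurve:
    """Omnibus power as a function of the number of trials."""

    n_values: list[int]
    power: list[float]
    alpha: float
    iterations: int
    seed: int | None = None

    def smallest_n_reaching(self, target: float) -> int | None:
        """Smallest simulated n whose estimated power reaches ``target``."""
        for n, p in zip(self.n_values, self.power):
            if p >= target:
                return n
        return None


def continuum_power(null_model: ContinuumModel, alt_model: ContinuumModel,
                    n_values, alpha: float = 0.05, iterations: int = 1000,
                    seed: int | None = None) -> PowerCurve:
    """Classical omnibus power over a grid of sample sizes.

    For each n, ``iterations`` paired datasets are simulated -- condition A
    from the null model, condition B from the alternative -- and tested
    with the classical SPM{t} paired test at level ``alpha``.  Power is
    the fraction of simulations producing at least one supra-threshold
    cluster anywhere along the continuum (omnibus rejection).  With
    ``alt_model = null_model`` this estimates the field-wide false
    positive rate, which should sit near ``alpha``.
    """
    if null_model.noise.Q != alt_model.noise.Q:
        raise ValueError("null and alternative models must share Q")
    rng = np.random.default_rng(seed)
    powers = []
    n_values = [int(n) for n in n_values]
    for n in n_values:
        hits = 0
        for _ in range(iterations):
            a = TrajectorySet(values=null_model.sample(rng, n), label="A")
            b = TrajectorySet(values=alt_model.sample(rng, n), label="B")
            if spm_t_test(a, b, design="paired", alpha=alpha).rejects:
                hits += 1
        powers.append(hits / iterations)
    return PowerCurve(n_values=n_values, power=powers, alpha=alpha,
                      iterations=iterations, seed=seed)
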