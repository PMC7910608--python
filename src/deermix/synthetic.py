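"""Seeded synthetic DEER traces for the docked/undocked two-state system.

The C-terminal tail (CTT) of Drosophila cryptochrome sits docked against
the flavin in the dark and releases upon photoreduction.  The flavin to
spin-label distance distribution is modelled as a mixture of two Gaussian
components: a docked state (mean 29.3 A, sigma 2.0 A, the NSQ-forming
L405E/C416N dark proxy) and an undocked state (mean 39.5 A, sigma 6.7 A,
the ASQ-forming light state).  The packaged registry lists the His378
variants with their undocked fractions, plus the small flavoprotein iLOV
with a C-terminal label as a single broad component (mean 44 A, sigma
12 A).  The quoted widths are Gaussian standard deviations, matching the
<R>/sigma parameterization of the mixture fit; they are not FWHM values.

Traces are generated by the forward model and perturbed with i.i.d.
Gaussian noise of standard deviation V(0)/SNR; every draw is controlled by
an explicit integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .forward import (
    AcquisitionModel,
    DeerTrace,
    DistanceDistribution,
    DistanceGrid,
    simulate_trace,
)

__all__ = [
    "GaussianComponent",
    "VariantSpec",
    "NoiseModel",
    "gaussian_distribution",
    "two_state_distribution",
    "add_noise",
    "load_registry",
    "variant_trace",
    "DOCKED",
    "UNDOCKED",
    "ILOV",
]


@dataclass(frozen=True)
class GaussianComponent:
    """One conformational state's distance component: mean <R> and width sigma (A)."""

    mean: float
    sigma: float
    label: str = "other"

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("component mean must be positive")
        if self.sigma <= 0:
            raise ValueError("component sigma must be positive")


@dataclass(frozen=True)
class VariantSpec:
    """Registry entry: radical type, the two fixed components, undocked fraction.

    A single-component case (e.g. iLOV) sets ``docked`` to None and
    ``fraction_undocked`` to 1.
    """

    name: str
    radical: str
    docked: GaussianComponent | None
    undocked: GaussianComponent
    fraction_undocked: float

    def __post_init__(self):
        if self.radical not in ("ASQ", "NSQ"):
            raise ValueError("radical must be ASQ or NSQ")
        if not 0.0 <= self.fraction_undocked <= 1.0:
            raise ValueError("fraction_undocked must be in [0, 1]")
        if self.docked is not None and self.docked == self.undocked:
            raise ValueError("docked and undocked components must differ")

    def distribution(self, grid: DistanceGrid) -> DistanceDistribution:
        if self.docked is None:
            return gaussian_distribution(self.undocked, grid)
        return two_state_distribution(self.fraction_undocked, self.docked, self.undocked, grid)


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian noise at a given SNR = V(0) / sd, seeded."""

    snr: float
    seed: int

    def __post_init__(self):
        if not self.snr > 0:
            raise ValueError("snr must be positive")


def gaussian_distribution(comp: GaussianComponent, grid: DistanceGrid) -> DistanceDistribution:
    """Gaussian component truncated to the grid and renormalized."""
    z = (grid.r - comp.mean) / comp.sigma
    return DistanceDistribution.from_unnormalized(grid, np.exp(-0.5 * z**2))


def two_state_distribution(
    fraction_undocked: float,
    docked: GaussianComponent,
    undocked: GaussianComponent,
    grid: DistanceGrid,
) -> DistanceDistribution:
    """Mixture (1 - f) * docked + f * undocked, each component renormalized on the grid.

    Renormalizing the components separately keeps ``fraction_undocked``
    exactly equal to the probability mass of the undocked state even after
    grid truncation.
    """
    if not 0.0 <= fraction_undocked <= 1.0:
        raise ValueError("fraction_undocked must be in [0, 1]")
    p_d = gaussian_distribution(docked, grid).density
    p_u = gaussian_distribution(undocked, grid).density
    mix = (1.0 - fraction_undocked) * p_d + fraction_undocked * p_u
    return DistanceDistribution(grid, mix)


def add_noise(trace: DeerTrace, noise: NoiseModel) -> DeerTrace:
    """Return a copy of ``trace`` with i.i.d. Gaussian noise of sd V(0)/snr added.

    Fully reproducible: the same ``NoiseModel`` always produces the same draw.
    """
    sd = float(trace.signal[0]) / noise.snr
    rng = np.random.default_rng(noise.seed)
    noisy = trace.signal + rng.normal(0.0, sd, size=trace.signal.shape)
    meta = dict(trace.meta)
    meta.update(snr=noise.snr, seed=noise.seed)
    return DeerTrace(trace.times.copy(), noisy, noise_sd=sd, meta=meta)


def _load_raw() -> dict:
    with resources.files("deermix.data").joinpath("variants.json").open() as fh:
        return json.load(fh)


def load_registry() -> dict[str, VariantSpec]:
    """Load the packaged variant registry as a name -> VariantSpec mapping."""
    raw = _load_raw()
    comps = {
        key: GaussianComponent(c["mean"], c["sigma"], c["label"])
        for key, c in raw["components"].items()
    }
    registry = {}
    for row in raw["variants"]:
        registry[row["name"]] = VariantSpec(
            name=row["name"],
            radical=row["radical"],
            docked=comps[row["docked"]] if row["docked"] is not None else None,
            undocked=comps[row["undocked"]],
            fraction_undocked=row["fraction_undocked"],
        )
    return registry


_COMPONENTS = {
    key: GaussianComponent(c["mean"], c["sigma"], c["label"])
    for key, c in _load_raw()["components"].items()
}
DOCKED: GaussianComponent = _COMPONENTS["docked"]
UNDOCKED: GaussianComponent = _COMPONENTS["undocked"]
ILOV: GaussianComponent = _COMPONENTS["ilov"]


def variant_trace(
    name: str,
    acq: AcquisitionModel,
    times,
    noise: NoiseModel | None = None,
    grid: DistanceGrid | None = None,
) -> DeerTrace:
    """Simulate a (optionally noisy) trace for a named registry variant.

    Metadata records the variant name and the generating undocked fraction.
    """
    registry = load_registry()
    if name not in registry:
        known = ", ".join(sorted(registry))
        raise KeyError(f"unknown variant {name!r}; known variants: {known}")
    spec = registry[name]
    grid = grid or DistanceGrid.default()
    trace = simulate_trace(spec.distribution(grid), acq, times)
    trace.meta.update(variant=name, radical=spec.radical, fraction_undocked=spec.fraction_undocked)
    if noise is not None:
        trace = add_noise(trace, noise)
    return trace
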