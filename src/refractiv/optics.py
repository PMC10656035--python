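"""One-photon light transport and opsin photocurrent model.

Light leaving an optical fiber is attenuated by Kubelka-Munk diffuse
scattering, T(r) = 1 / (S r + 1), combined with geometric (conical) spread,
so the intensity relative to the fiber tip is

    I(r) / I(0) = rho^2 / ((S r + 1) (r + rho)^2),
    rho = (d / 2) * sqrt((n / NA)^2 - 1),

with d the fiber diameter, NA its numerical aperture and n the refractive
index of gray matter.  Peak opsin photocurrent follows a Hill equation
P(I) = I_max I^h / (K^h + I^h).  Because the number of neurons in a
spherical slice grows like r^2 while the photocurrent falls slower than
r^-2 (Hill exponent < 1), the summed photocurrent per slice *increases*
with distance: widefield optogenetics is not a local technique.

Note on parameters: the source tabulates the fiber radius as "0.1 um"; a
0.2-um fiber is physically implausible and the geometry formula uses the
fiber diameter in mm, so the value is read as 0.1 mm (100-um radius fiber),
treating the printed unit as an erratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FiberSpec",
    "OpsinSpec",
    "transmission",
    "relative_intensity",
    "photocurrent",
    "shell_activation_profile",
    "assign_stimulus_gains",
]


@dataclass(frozen=True)
class FiberSpec:
    """Optical fiber and tissue parameters (defaults: mouse gray matter)."""

    scattering_S: float = 10.3      # 1/mm
    fiber_radius: float = 0.1       # mm
    numerical_aperture: float = 0.37
    refraction_n: float = 1.36
    source_intensity: float = 10.0  # mW/mm^2 at the fiber tip
    depth: float = 0.7              # mm, tissue depth for neuron placement
    neuron_density: float = 1960.0  # neurons/mm^3

    def __post_init__(self):
        for name in ("scattering_S", "fiber_radius", "numerical_aperture",
                     "refraction_n", "source_intensity", "depth",
                     "neuron_density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.numerical_aperture >= self.refraction_n:
            raise ValueError("NA must be below the tissue refractive index")

    @property
    def rho(self) -> float:
        """Geometric spread constant (mm)."""
        return self.fiber_radius * np.sqrt(
            (self.refraction_n / self.numerical_aperture) ** 2 - 1.0
        )

    @property
    def cone_half_angle(self) -> float:
        """Half-angle (rad) of the acceptance cone, asin(NA / n)."""
        return float(np.arcsin(self.numerical_aperture / self.refraction_n))


@dataclass(frozen=True)
class OpsinSpec:
    """Hill-equation photocurrent parameters (ChR2 fit)."""

    I_max: float = 642.0   # pA
    hill_n: float = 0.76
    half_sat_K: float = 0.84  # mW/mm^2

    def __post_init__(self):
        if min(self.I_max, self.hill_n, self.half_sat_K) <= 0:
            raise ValueError("opsin parameters must be positive")


def transmission(distance, fiber: FiberSpec):
    """Kubelka-Munk transmission fraction T = 1 / (S r + 1)."""
    r = np.asarray(distance, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    return 1.0 / (fiber.scattering_S * r + 1.0)


def relative_intensity(distance, fiber: FiberSpec):
    """I(r)/I(0): scattering times conical geometric loss; 1 at r = 0."""
    r = np.asarray(distance, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    rho = fiber.rho
    return transmission(r, fiber) * rho**2 / (r + rho) ** 2


def photocurrent(intensity, opsin: OpsinSpec):
    """Peak photocurrent (pA) from the Hill equation; saturates at I_max."""
    I = np.asarray(intensity, dtype=float)
    if np.any(I < 0):
        raise ValueError("intensity must be >= 0")
    In = np.power(I, opsin.hill_n)
    return opsin.I_max * In / (opsin.half_sat_K**opsin.hill_n + In)


def shell_activation_profile(
    fiber: FiberSpec,
    opsin: OpsinSpec,
    n_shells: int = 15,
    max_depth: float = 1.0,
):
    """Per-shell neuron counts, light intensity and summed photocurrent.

    Neurons are distributed uniformly over ``n_shells`` spherical slices of
    equal thickness spanning [0, max_depth], each slice truncated to the
    cone of light (half-angle asin(NA/n)); the per-shell count is therefore
    proportional to r^2 at fixed cone fraction.  Intensity is evaluated at
    the shell midpoint.  Returns a DataFrame with columns distance_mm,
    intensity_rel, intensity_mw_mm2, neuron_count, photocurrent_pA and
    shell_total (count x photocurrent).
    """
    import pandas as pd

    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    edges = np.linspace(0.0, max_depth, n_shells + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    cone_fraction = 0.5 * (1.0 - np.cos(fiber.cone_half_angle))
    volumes = cone_fraction * 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    counts = fiber.neuron_density * volumes
    rel = relative_intensity(mids, fiber)
    inten = fiber.source_intensity * rel
    pcur = photocurrent(inten, opsin)
    return pd.DataFrame(
        {
            "distance_mm": mids,
            "intensity_rel": rel,
            "intensity_mw_mm2": inten,
            "neuron_count": counts,
            "photocurrent_pA": pcur,
            "shell_total": counts * pcur,
        }
    )


def assign_stimulus_gains(
    n_neurons: int,
    fiber: FiberSpec,
    opsin: OpsinSpec,
    rng: np.random.Generator,
    ceiling: float = 1.0,
    max_depth: float | None = None,
) -> np.ndarray:
    """Distance-distributed stimulus gains in [0, ceiling], one per neuron.

    Each neuron receives a random distance from the fiber tip, uniform over
    the illuminated (cone-truncated) volume, i.e. density proportional to
    r^2 on [0, max_depth]; its gain is the Hill photocurrent at the local
    intensity rescaled so that a neuron at the tip would sit at ``ceiling``
    (gains are fixed across trials; the stimulus amplitude gamma_S sets the
    drive a full-gain neuron receives).
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    R = fiber.depth if max_depth is None else max_depth
    distances = R * np.cbrt(rng.random(n_neurons))
    inten = fiber.source_intensity * relative_intensity(distances, fiber)
    p = photocurrent(inten, opsin)
    p_max = photocurrent(fiber.source_intensity, opsin)
    return ceiling * p / p_max


def gain_cdf(g, fiber: FiberSpec, opsin: OpsinSpec, ceiling: float = 1.0,
             max_depth: float | None = None):
    """Analytic CDF of `assign_stimulus_gains` draws (for model checking).

    The gain is a monotone decreasing map of distance, and distance has CDF
    (r/R)^3, so P(G <= g) = 1 - (r(g)/R)^3 with r(g) found by bisection.
    """
    from scipy.optimize import brentq

    R = fiber.depth if max_depth is None else max_depth
    p_max = photocurrent(fiber.source_intensity, opsin)

    def gain_at(r):
        return ceiling * photocurrent(
            fiber.source_intensity * relative_intensity(r, fiber), opsin
        ) / p_max

    g = np.atleast_1d(np.asarray(g, dtype=float))
    lo, hi = gain_at(R), gain_at(0.0)
    out = np.empty_like(g)
    for k, gv in enumerate(g):
        if gv <= lo:
            out[k] = 0.0
        elif gv >= hi:
            out[k] = 1.0
        else:
            r = brentq(lambda x: gain_at(x) - gv, 0.0, R)
            out[k] = 1.0 - (r / R) ** 3
    return out
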