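"""Synthetic structures and scattering data.

Everything here is a pure function of its arguments including the seed.
Curves default to the instrument-like q-range 0.008-0.34 1/A (200 points)
and carry Gaussian noise with a recorded sigma(q) = rel*I(q) + abs, so
that chi computed against the recorded uncertainties is exactly
calibrated (mean chi = 1 against the truth).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .scatter import ScatteringCurve, debye_intensity
from .structures import RigidBodyAssembly, Structure

__all__ = [
    "NoiseModel",
    "default_q_grid",
    "make_bead_sphere",
    "make_two_lobe_dimer",
    "simulate_curve",
    "attach_uncertainties",
    "write_sidecar",
]

#: Instrument-like momentum-transfer range, 1/A.
Q_MIN, Q_MAX, N_Q = 0.008, 0.34, 200

#: Default planted-dimer fixture: two bead spheres, prolate overall.
DEFAULT_LOBE_RADIUS = 15.0
DEFAULT_SEPARATION = 32.0
DEFAULT_BEADS_PER_LOBE = 800


def default_q_grid(n: int = N_Q) -> np.ndarray:
    return np.linspace(Q_MIN, Q_MAX, n)


@dataclass(frozen=True)
class NoiseModel:
    """Counting-statistics-like uncertainty: sigma(q) = rel*I(q) + abs.

    Perturbations are Gaussian with that sigma (matching the chi fitting
    model, which uses the recorded sigma), seeded for reproducibility.
    """

    relative_floor: float = 0.01
    absolute_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_floor < 0 or self.absolute_floor < 0:
            raise ValueError("noise floors must be >= 0")
        if self.relative_floor == 0 and self.absolute_floor == 0:
            raise ValueError("at least one noise floor must be positive")

    def sigma(self, intensity: np.ndarray) -> np.ndarray:
        return self.relative_floor * np.abs(intensity) + self.absolute_floor


def make_bead_sphere(radius: float, n_beads: int, seed: int,
                     component_id: str = "A") -> Structure:
    """Unit-weight beads uniform in a ball of the given radius (A).

    Rejection sampling from the enclosing cube; reproducible from seed.
    """
    if radius <= 0 or n_beads < 1:
        raise ValueError("radius must be > 0 and n_beads >= 1")
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 3))
    while len(pts) < n_beads:
        cand = rng.uniform(-radius, radius, size=(2 * n_beads, 3))
        keep = (cand ** 2).sum(axis=1) <= radius ** 2
        pts = np.vstack([pts, cand[keep]])
    coords = pts[:n_beads]
    return Structure.from_arrays(coords, component_id=component_id,
                                 name=f"sphere(R={radius:g},n={n_beads},seed={seed})")


def make_two_lobe_dimer(lobe_radius: float = DEFAULT_LOBE_RADIUS,
                        separation: float = DEFAULT_SEPARATION,
                        n_beads_per_lobe: int = DEFAULT_BEADS_PER_LOBE,
                        seed: int = 0) -> RigidBodyAssembly:
    """Planted two-lobe dimer: bead-sphere components A and B with
    centroids ``separation`` apart along x, identity transforms.

    A prolate assembly of two equal lobes, sized like a small-protein
    dimer envelope; the default scale keeps Debye evaluation fast.
    """
    rng = np.random.default_rng(seed)
    seed_a, seed_b = (int(x) for x in rng.integers(0, 2 ** 31 - 1, size=2))
    lobe_a = make_bead_sphere(lobe_radius, n_beads_per_lobe, seed_a, component_id="A")
    lobe_b = make_bead_sphere(lobe_radius, n_beads_per_lobe, seed_b, component_id="B")
    lobe_b = lobe_b.with_coords(lobe_b.coords + np.array([separation, 0.0, 0.0]))
    return RigidBodyAssembly({"A": lobe_a, "B": lobe_b})


def simulate_curve(source, q_grid=None, noise: NoiseModel | None = None,
                   background: float = 0.0) -> ScatteringCurve:
    """Simulate a 1-D scattering curve from structures.

    ``source`` is a single :class:`Structure` or a list of
    ``(weight, Structure)`` pairs with non-negative weights;
    I(q) = sum_k weight_k * Debye_k(q) + background.  With a
    :class:`NoiseModel`, Gaussian noise of sigma(q) = rel*I + abs is added
    and that sigma is recorded in the curve; without one, sigma is a
    nominal 1.
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    if isinstance(source, Structure):
        source = [(1.0, source)]
    intensity = np.full_like(q, float(background))
    for weight, structure in source:
        if weight < 0:
            raise ValueError("mixture weights must be non-negative")
        intensity = intensity + weight * debye_intensity(structure.coords,
                                                         structure.weights, q)
    if noise is None:
        return ScatteringCurve(q, intensity, np.ones_like(q))
    sigma = noise.sigma(intensity)
    rng = np.random.default_rng(noise.seed)
    noisy = intensity + rng.normal(0.0, 1.0, size=len(q)) * sigma
    return ScatteringCurve(q, noisy, sigma)


def attach_uncertainties(curve: ScatteringCurve, noise: NoiseModel) -> ScatteringCurve:
    """Record a noise model's sigma band on a curve without perturbing it.

    Used for noiseless planted-truth tests where chi must still be
    measured against a realistic uncertainty scale.
    """
    return curve.with_sigma(noise.sigma(curve.I))


def write_sidecar(path, **params) -> None:
    """Write generator parameters (the planted truth) as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
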