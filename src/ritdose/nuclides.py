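"""Radionuclide decay data and beta-minus spectrum construction.

The physical source terms of the dosimetry chain live here: half-lives and
decay constants used for decay correction and surrogate-nuclide
extrapolation, and the beta spectra that feed the Monte Carlo transport.

Spectra use the allowed beta shape

    N(E) dE  ~  p * W * (W0 - W)^2 * F(Z, W) dE

with ``W`` the total electron energy in electron-mass units, ``p`` the
momentum in the same units, ``W0`` the endpoint and ``F`` the nonrelativistic
Fermi function of the daughter nucleus.  The Coulomb correction ``F`` can be
switched off, in which case the density reduces to the bare statistical
shape, convenient for analytic cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Radionuclide",
    "BetaBranch",
    "BetaSpectrum",
    "UnknownNuclideError",
    "NuclideValidationError",
    "UnsupportedNuclideError",
    "load_registry",
    "load_nuclide",
    "decay_factor",
    "build_beta_spectrum",
    "sample_beta_energy",
    "mean_energy_per_decay",
]

LN2 = math.log(2.0)
#: keV -> J
KEV_TO_J = 1.602176634e-16
#: electron rest energy in keV
ELECTRON_MASS_KEV = 510.99895
#: fine-structure constant
ALPHA_FS = 7.2973525693e-3


class UnknownNuclideError(KeyError):
    """Requested nuclide is not present in the registry."""


class NuclideValidationError(ValueError):
    """Registry entry violates the nuclide invariants."""


class UnsupportedNuclideError(ValueError):
    """Operation requires beta branches the nuclide does not have."""


@dataclass(frozen=True)
class BetaBranch:
    """A single beta-minus branch: endpoint energy [keV], fraction per decay."""

    endpoint_kev: float
    fraction: float

    def __post_init__(self) -> None:
        if not self.endpoint_kev > 0:
            raise NuclideValidationError(
                f"branch endpoint must be positive, got {self.endpoint_kev}"
            )
        if not (0.0 < self.fraction <= 1.0):
            raise NuclideValidationError(
                f"branch fraction must be in (0, 1], got {self.fraction}"
            )


@dataclass(frozen=True)
class Radionuclide:
    """Decay data for one radionuclide.

    Attributes
    ----------
    name : str
        Registry identifier, e.g. ``"Lu-177"``.
    half_life_h : float
        Physical half-life [h].
    beta_branches : tuple of BetaBranch
        Beta-minus branches; empty for pure EC/gamma emitters such as In-111.
    daughter_z : int or None
        Daughter atomic number, used in the Fermi Coulomb correction.
    """

    name: str
    half_life_h: float
    beta_branches: tuple[BetaBranch, ...] = ()
    daughter_z: int | None = None

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise NuclideValidationError(
                f"{self.name}: half-life must be positive, got {self.half_life_h}"
            )
        total = sum(b.fraction for b in self.beta_branches)
        if total > 1.0 + 1e-12:
            raise NuclideValidationError(
                f"{self.name}: branch fractions sum to {total} > 1"
            )

    @property
    def decay_constant(self) -> float:
        """Physical decay constant lambda = ln 2 / T1/2 [1/h]."""
        return LN2 / self.half_life_h

    @property
    def beta_yield(self) -> float:
        """Beta particles emitted per decay (sum of branch fractions)."""
        return sum(b.fraction for b in self.beta_branches)

    @property
    def max_endpoint_kev(self) -> float:
        if not self.beta_branches:
            return 0.0
        return max(b.endpoint_kev for b in self.beta_branches)


@dataclass(frozen=True)
class BetaSpectrum:
    """Discretized beta energy spectrum (per emitted beta particle).

    ``density`` is a probability density per keV on ``energy_grid`` whose
    trapezoid integral is 1; ``cdf`` is the matching cumulative distribution.
    """

    energy_grid: np.ndarray
    density: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.energy_grid, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        cdf = np.asarray(self.cdf, dtype=float)
        if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
            raise ValueError("energy grid must be strictly increasing 1-D")
        if dens.shape != grid.shape or cdf.shape != grid.shape:
            raise ValueError("density/cdf must match the energy grid")
        if np.any(dens < -1e-15):
            raise ValueError("density must be nonnegative")
        norm = np.trapezoid(dens, grid)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"density integrates to {norm}, expected 1 +- 1e-6")
        if np.any(np.diff(cdf) < -1e-12) or abs(cdf[-1] - 1.0) > 1e-9:
            raise ValueError("cdf must be monotone and end at 1")
        object.__setattr__(self, "energy_grid", grid)
        object.__setattr__(self, "density", dens)
        object.__setattr__(self, "cdf", cdf)

    def mean(self) -> float:
        """Mean energy per emitted beta [keV], trapezoid rule on the grid."""
        return float(np.trapezoid(self.energy_grid * self.density, self.energy_grid))


def _default_registry_path() -> Path:
    return Path(str(resources.files("ritdose").joinpath("data/nuclides.yaml")))


def load_registry(path: str | Path | None = None) -> dict:
    """Load a nuclide registry mapping from YAML (package default if None)."""
    p = Path(path) if path is not None else _default_registry_path()
    with open(p, "r", encoding="utf-8") as fh:
        registry = yaml.safe_load(fh)
    if not isinstance(registry, Mapping):
        raise NuclideValidationError(f"registry {p} is not a mapping")
    return dict(registry)


def load_nuclide(name: str, registry: Mapping | str | Path | None = None) -> Radionuclide:
    """Look up ``name`` in the registry and return a validated Radionuclide.

    ``registry`` may be a mapping (already loaded), a path to a YAML file, or
    None for the built-in defaults (In-111, Lu-177, Y-90, I-131).
    """
    if registry is None or isinstance(registry, (str, Path)):
        registry = load_registry(registry)
    if name not in registry:
        available = ", ".join(sorted(registry))
        raise UnknownNuclideError(
            f"unknown nuclide {name!r}; available: {available}"
        )
    entry = registry[name]
    try:
        branches = tuple(
            BetaBranch(float(b["emax_kev"]), float(b["fraction"]))
            for b in entry.get("branches", [])
        )
        return Radionuclide(
            name=name,
            half_life_h=float(entry["half_life_h"]),
            beta_branches=branches,
            daughter_z=entry.get("daughter_z"),
        )
    except (KeyError, TypeError) as exc:
        raise NuclideValidationError(f"malformed registry entry for {name!r}: {exc}")


def decay_factor(nuclide: Radionuclide, t_h: float | np.ndarray) -> float | np.ndarray:
    """Fraction of activity remaining after ``t_h`` hours: exp(-lambda t)."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative for decay_factor")
    out = np.exp(-nuclide.decay_constant * t)
    return float(out) if np.isscalar(t_h) else out


def _fermi_function(z_daughter: int, w: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Nonrelativistic Fermi Coulomb correction F(Z, W) for beta-minus."""
    eta = np.where(p > 0, ALPHA_FS * z_daughter * w / np.maximum(p, 1e-300), 0.0)
    x = 2.0 * math.pi * eta
    denom = -np.expm1(-x)
    with np.errstate(over="ignore", invalid="ignore"):
        f = np.where(x > 0, x / np.where(denom > 0, denom, 1.0), 1.0)
    return f


def _branch_shape(
    e_kev: np.ndarray, emax_kev: float, daughter_z: int | None, coulomb: bool
) -> np.ndarray:
    """Unnormalized allowed-shape density of one branch on grid ``e_kev``."""
    w = 1.0 + e_kev / ELECTRON_MASS_KEV
    w0 = 1.0 + emax_kev / ELECTRON_MASS_KEV
    p = np.sqrt(np.maximum(w * w - 1.0, 0.0))
    shape = p * w * np.square(np.maximum(w0 - w, 0.0))
    if coulomb and daughter_z:
        shape = shape * _fermi_function(daughter_z, w, p)
    shape[e_kev >= emax_kev] = 0.0
    return shape


def build_beta_spectrum(
    nuclide: Radionuclide, n_bins: int = 2048, coulomb: bool = True
) -> BetaSpectrum:
    """Branch-fraction-weighted allowed beta spectrum on a uniform grid.

    The density is normalized per emitted beta particle (branch weights are
    rescaled to sum to 1); multiply means by ``nuclide.beta_yield`` to get
    per-decay quantities.
    """
    if n_bins < 50:
        raise ValueError("n_bins must be >= 50")
    if not nuclide.beta_branches:
        raise UnsupportedNuclideError(
            f"{nuclide.name} has no beta branches (not a beta-minus emitter)"
        )
    emax = nuclide.max_endpoint_kev
    grid = np.linspace(0.0, emax, n_bins + 1)
    dens = np.zeros_like(grid)
    total_fraction = nuclide.beta_yield
    for branch in nuclide.beta_branches:
        shape = _branch_shape(grid, branch.endpoint_kev, nuclide.daughter_z, coulomb)
        norm = np.trapezoid(shape, grid)
        if norm <= 0:
            raise NuclideValidationError(
                f"{nuclide.name}: degenerate branch at {branch.endpoint_kev} keV"
            )
        dens += (branch.fraction / total_fraction) * shape / norm
    dens /= np.trapezoid(dens, grid)
    # trapezoid cumulative integral
    seg = 0.5 * (dens[1:] + dens[:-1]) * np.diff(grid)
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    cdf /= cdf[-1]
    return BetaSpectrum(energy_grid=grid, density=dens, cdf=cdf)


def sample_beta_energy(
    spectrum: BetaSpectrum, rng: int | np.random.Generator, n: int
) -> np.ndarray:
    """Inverse-CDF sampling of beta energies [keV]; reproducible per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    u = gen.random(n)
    return np.interp(u, spectrum.cdf, spectrum.energy_grid)


def mean_energy_per_decay(
    nuclide: Radionuclide, n_bins: int = 2048, coulomb: bool = True
) -> float:
    """Mean beta energy emitted per decay, Delta [keV/decay]."""
    spectrum = build_beta_spectrum(nuclide, n_bins=n_bins, coulomb=coulomb)
    return spectrum.mean() * nuclide.beta_yield
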