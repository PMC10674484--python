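"""Synthetic inputs for every stage of the aggregation-analysis chain.

The generators emulate the statistical structure of the real measurements
so the whole pipeline can run and be validated with no instrument data:

* TCSPC decays: a multi-exponential mean (optionally convolved with a
  Gaussian instrument response) scaled to a target peak count, with
  Poisson counting noise per channel;
* polarized intensity pairs consistent with a prescribed steady-state
  anisotropy;
* pyrene I1/I3 titrations: piecewise-linear in log10(concentration) with
  a single breakpoint at the critical aggregation concentration;
* coordinate fixtures (regular helices, uniform balls) whose gyration
  and Kirkwood radii are known in closed form.

Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .cac import TitrationSeries
from .decay import DecayTrace
from .structure import Trajectory, write_pdb

__all__ = [
    "DecaySimSpec",
    "TitrationSimSpec",
    "GeometryFixture",
    "generate_decay",
    "generate_anisotropy_pair",
    "generate_titration",
    "build_helix",
    "sample_uniform_ball",
    "write_geometry_pdb",
]


@dataclass(frozen=True)
class DecaySimSpec:
    """Recipe for a synthetic TCSPC trace.

    Defaults reproduce the measurement conditions of the tryptophan decay
    this package targets: a 50 ns window over 1024 channels, three
    lifetime components, ~1 ns excitation pulse, 1e4 counts at maximum.
    """

    components: Tuple[Tuple[float, float], ...] = (
        (0.45, 1.22), (0.41, 3.66), (0.14, 7.40),
    )
    irf_width_ns: float = 0.4
    time_window_ns: float = 50.0
    n_channels: int = 1024
    peak_counts: float = 1e4
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        comps = tuple((float(w), float(tau)) for w, tau in self.components)
        object.__setattr__(self, "components", comps)
        weights = [w for w, _ in comps]
        taus = [tau for _, tau in comps]
        if any(w <= 0 for w in weights):
            raise ValueError("component weights must be strictly positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {sum(weights)}")
        if any(tau <= 0 for tau in taus):
            raise ValueError("lifetimes must be strictly positive")
        if len(set(taus)) != len(taus):
            raise ValueError("lifetimes must be distinct")
        if self.time_window_ns <= 0:
            raise ValueError(f"time_window_ns must be > 0, got {self.time_window_ns}")
        if self.irf_width_ns < 0:
            raise ValueError(f"irf_width_ns must be >= 0, got {self.irf_width_ns}")
        if self.n_channels < 64:
            raise ValueError(f"n_channels must be >= 64, got {self.n_channels}")
        if self.peak_counts <= 0:
            raise ValueError(f"peak_counts must be > 0, got {self.peak_counts}")
        if self.background < 0:
            raise ValueError(f"background must be >= 0, got {self.background}")


def generate_decay(spec: DecaySimSpec, noise: bool = True) -> DecayTrace:
    """Simulate a photon-counting decay histogram.

    The mean curve is the weighted sum of exponentials, convolved with a
    normalised Gaussian IRF when ``irf_width_ns > 0`` (edge effects are
    ignored: the window is much longer than the lifetimes), scaled so its
    maximum equals ``peak_counts``, plus the constant background.  With
    ``noise`` each channel is an independent Poisson draw from that mean;
    without, the mean itself is returned (exact round-trip through the
    fitter).
    """
    dt = spec.time_window_ns / spec.n_channels
    times = np.arange(spec.n_channels) * dt
    weights = np.array([w for w, _ in spec.components])
    taus = np.array([tau for _, tau in spec.components])
    decay = np.sum(weights[:, None] * np.exp(-times[None, :] / taus[:, None]), axis=0)
    irf = None
    if spec.irf_width_ns > 0:
        center = 5.0 * spec.irf_width_ns
        kernel = np.exp(-0.5 * ((times - center) / spec.irf_width_ns) ** 2)
        kernel /= kernel.sum()
        decay = np.convolve(kernel, decay)[: spec.n_channels]
        irf = kernel * (spec.peak_counts / kernel.max())
    mean = decay * (spec.peak_counts / decay.max()) + spec.background
    if noise:
        rng = np.random.default_rng(spec.seed)
        counts = rng.poisson(mean).astype(float)
    else:
        counts = mean
    return DecayTrace(times_ns=times, counts=counts, irf=irf,
                      metadata={"seed": spec.seed, "synthetic": True})


def generate_anisotropy_pair(
    r_true: float,
    total_intensity: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Tuple[float, float]:
    """Polarized intensities (Ivv, Ivh) consistent with anisotropy ``r_true``.

    Noiseless means satisfy Ivv + 2 Ivh = total and
    (Ivv - Ivh)/(Ivv + 2 Ivh) = r_true; ``noise_sd`` applies independent
    Gaussian relative noise to each channel.
    """
    if not -0.2 <= r_true < 1.0:
        raise ValueError(f"r_true must lie in [-0.2, 1), got {r_true}")
    if total_intensity <= 0:
        raise ValueError(f"total_intensity must be > 0, got {total_intensity}")
    ivv = total_intensity * (1.0 + 2.0 * r_true) / 3.0
    ivh = total_intensity * (1.0 - r_true) / 3.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ivv *= 1.0 + rng.normal(0.0, noise_sd)
        ivh *= 1.0 + rng.normal(0.0, noise_sd)
    return float(ivv), float(ivh)


@dataclass(frozen=True)
class TitrationSimSpec:
    """Recipe for a pyrene I1/I3 titration.

    Defaults emulate the assay this package targets: twelve log-spaced
    points over 0.2-21 uM, a breakpoint at 4.3 uM, a near-flat polar
    plateau at 1.80 and a steep descending apolar branch.  The noise level
    is a convention (the assay's actual scatter is not published).
    """

    concentrations_uM: Optional[Tuple[float, ...]] = None
    breakpoint_uM: float = 4.3
    plateau_ratio: float = 1.80
    slope_below: float = -0.02
    slope_above: float = -0.60
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concentrations_uM is None:
            conc = np.logspace(math.log10(0.2), math.log10(21.0), 12)
            object.__setattr__(self, "concentrations_uM", tuple(conc))
        conc = np.asarray(self.concentrations_uM, dtype=float)
        if len(conc) < 6:
            raise ValueError(f"need at least 6 concentrations, got {len(conc)}")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        if not conc.min() < self.breakpoint_uM < conc.max():
            raise ValueError(
                f"breakpoint_uM={self.breakpoint_uM} outside the concentration "
                f"range [{conc.min()}, {conc.max()}]"
            )
        n_below = int(np.sum(conc < self.breakpoint_uM))
        n_above = int(np.sum(conc > self.breakpoint_uM))
        if n_below < 2 or n_above < 2:
            raise ValueError(
                f"need at least 2 points on each side of the breakpoint "
                f"(have {n_below} below, {n_above} above)"
            )
        if not self.slope_above < self.slope_below:
            raise ValueError(
                "slope_above must be smaller than slope_below "
                "(the apolar branch descends more steeply)"
            )
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_titration(spec: TitrationSimSpec) -> TitrationSeries:
    """Simulate an I1/I3 titration: two lines meeting at the breakpoint.

    ratio(c) = plateau + slope * (log10 c - log10 cac), with the polar
    slope below and the apolar slope above the breakpoint, plus optional
    Gaussian noise.  Points are returned sorted by concentration.
    """
    conc = np.sort(np.asarray(spec.concentrations_uM, dtype=float))
    x = np.log10(conc)
    xb = math.log10(spec.breakpoint_uM)
    ratio = np.where(
        x <= xb,
        spec.plateau_ratio + spec.slope_below * (x - xb),
        spec.plateau_ratio + spec.slope_above * (x - xb),
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ratio = ratio + rng.normal(0.0, spec.noise_sd, size=len(ratio))
    return TitrationSeries(concentrations_uM=conc, ratios=ratio)


@dataclass(frozen=True)
class GeometryFixture:
    """A labelled point cloud with element symbols, masses and, where a
    closed form exists, reference Rg/Rh values with a provenance note."""

    label: str
    coordinates: np.ndarray
    elements: Tuple[str, ...]
    masses: np.ndarray
    reference_values: Optional[dict] = None

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coordinates, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 1:
            raise ValueError("coordinates must be an N x 3 array, N >= 1")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        m = np.asarray(self.masses, dtype=float)
        if m.shape != (xyz.shape[0],) or np.any(m <= 0):
            raise ValueError("masses must be positive, one per atom")
        object.__setattr__(self, "coordinates", xyz)
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "elements", tuple(self.elements))

    def to_trajectory(self, atom_name: str = "CA") -> Trajectory:
        n = len(self.coordinates)
        return Trajectory(
            frames=self.coordinates[None],
            elements=self.elements,
            masses=self.masses,
            atom_names=tuple([atom_name] * n),
            residue_ids=np.arange(1, n + 1),
        )


def build_helix(
    n_residues: int,
    rise_A: float = 1.5,
    radius_A: float = 2.3,
    twist_deg: float = 100.0,
) -> GeometryFixture:
    """A Calpha-only trace on a regular helix (alpha-helix defaults:
    1.5 Angstrom rise and 100 degrees twist per residue)."""
    if n_residues < 2:
        raise ValueError(f"n_residues must be >= 2, got {n_residues}")
    k = np.arange(n_residues)
    theta = np.deg2rad(twist_deg) * k
    xyz = np.column_stack([
        radius_A * np.cos(theta),
        radius_A * np.sin(theta),
        rise_A * k,
    ])
    return GeometryFixture(
        label=f"helix_{n_residues}",
        coordinates=xyz,
        elements=tuple(["C"] * n_residues),
        masses=np.ones(n_residues),
    )


def sample_uniform_ball(n_points: int, radius_A: float, seed: int = 0) -> GeometryFixture:
    """Points i.i.d. uniform in a solid ball.

    For n -> inf the descriptors approach closed forms:
    Rg -> radius * sqrt(3/5) and the Kirkwood Rh -> (5/6) * radius
    (the mean inverse distance of two uniform points in a ball is
    6/(5 R)); both are stored as reference values.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    if radius_A <= 0:
        raise ValueError(f"radius_A must be > 0, got {radius_A}")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=(n_points, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    radii = radius_A * rng.random(n_points) ** (1.0 / 3.0)
    xyz = direction * radii[:, None]
    return GeometryFixture(
        label=f"ball_{n_points}",
        coordinates=xyz,
        elements=tuple(["C"] * n_points),
        masses=np.ones(n_points),
        reference_values={
            "Rg_A": radius_A * math.sqrt(3.0 / 5.0),
            "Rh_A": radius_A * 5.0 / 6.0,
            "provenance": "closed forms for the uniform solid ball "
                          "(asymptotic in n_points)",
        },
    )


def write_geometry_pdb(fixture: GeometryFixture, path) -> None:
    """Write a geometry fixture as a single-MODEL PDB file."""
    write_pdb(fixture.to_trajectory(), path)
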