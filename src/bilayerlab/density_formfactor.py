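"""Density profiles along the membrane normal and SAXS form factors.

Number densities are accumulated on a fixed z-grid after re-centering each
frame on the bilayer center (mean phosphorus z by default) and wrapping into
[−Lz/2, Lz/2). Electron densities weight each atom by its electron count.
The X-ray form factor is the modulus of the 1-D Fourier transform of the
electron-density contrast across the bilayer,

    |F(q_z)| = | ∫ (ρₑ(z) − ρ_bulk) e^{i q_z z} dz |,

evaluated by rectangle-rule quadrature over the binned profile and, following
the convention used for comparing simulated and experimental lipid-bilayer
scattering, normalized by the height of the first peak found in the
q ∈ [0.1, 0.2] Å⁻¹ window. q is reported in Å⁻¹; lengths stay nm internally
with one conversion at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .exceptions import DomainError, NormalizationError, TopologyError
from .io_core import BilayerTopology, FrameSeries

#: particles per nm^3 in a 1 M solution (Avogadro constant / 1e24)
NM3_PER_MOLAR = 0.602214076


@dataclass(frozen=True)
class DensityProfile:
    """Species density vs z, origin at the bilayer center.

    ``density`` is per-bin in nm⁻³ for number densities, e·nm⁻³ for electron
    densities, or percent after concentration normalization. The bin volume
    (mean lateral area × bin width) is carried so particle-count closure can
    be checked: Σ density × bin_volume = mean particle count per frame.
    """

    species: str
    bin_centers: np.ndarray  # nm
    density: np.ndarray
    n_frames: int
    bin_volume: float  # nm^3
    units: str = "nm^-3"

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_centers)
        if widths.size and not np.allclose(widths, widths[0], rtol=1e-9):
            raise DomainError("bins must be equally spaced")
        if np.any(self.density < 0):
            raise DomainError("negative density")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    def total_count(self) -> float:
        """Mean particle (or electron) count per frame implied by the profile."""
        return float(np.sum(self.density) * self.bin_volume)


@dataclass(frozen=True)
class FormFactor:
    """Normalized SAXS form factor |F(q_z)| on an ascending q grid (Å⁻¹)."""

    q_grid: np.ndarray
    magnitude: np.ndarray
    raw_magnitude: np.ndarray  # before first-peak normalization, e/Å²

    def __post_init__(self) -> None:
        if np.any(self.magnitude < 0):
            raise DomainError("negative |F|")
        if self.q_grid[0] < 0 or np.any(np.diff(self.q_grid) <= 0):
            raise DomainError("q grid must ascend from 0")


def _resolve_center(
    frames: FrameSeries,
    topology: BilayerTopology | None,
    center: float | str | None,
) -> np.ndarray:
    """Per-frame z origin: a fixed value, the box middle, or an anchor-atom mean."""
    if center is None:
        return frames.box[:, 2] / 2.0
    if isinstance(center, (int, float)):
        return np.full(frames.n_frames, float(center))
    if topology is None:
        raise DomainError("anchor-based centering needs a topology")
    idx = [i for i, a in enumerate(topology.atoms) if a.atom_name == str(center)]
    if not idx:
        raise TopologyError(f"no atoms named {center!r} to center on")
    return frames.coords[:, idx, 2].mean(axis=1)


def _binned_profile(
    frames: FrameSeries,
    indices: np.ndarray,
    weights: np.ndarray | None,
    bin_width: float,
    centers_z: np.ndarray,
    species: str,
    units: str,
) -> DensityProfile:
    if bin_width <= 0:
        raise DomainError("bin_width must be > 0")
    if indices.size == 0:
        raise DomainError("empty atom selection")
    lz_max = float(frames.box[:, 2].max())
    n_bins = int(np.ceil(lz_max / bin_width))
    half = n_bins * bin_width / 2.0
    edges = np.linspace(-half, half, n_bins + 1)

    counts = np.zeros(n_bins)
    for f in range(frames.n_frames):
        lz = frames.box[f, 2]
        z = frames.coords[f, indices, 2] - centers_z[f]
        z = z - lz * np.round(z / lz)  # wrap into [-Lz/2, Lz/2)
        hist, _ = np.histogram(z, bins=edges, weights=weights)
        counts += hist
    area = float(np.mean(frames.box[:, 0] * frames.box[:, 1]))
    bin_volume = area * bin_width
    density = counts / (frames.n_frames * bin_volume)
    return DensityProfile(
        species=species,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=density,
        n_frames=frames.n_frames,
        bin_volume=bin_volume,
        units=units,
    )


def number_density(
    frames: FrameSeries,
    selection: Sequence[int] | np.ndarray | Callable,
    bin_width: float = 0.1,
    *,
    topology: BilayerTopology | None = None,
    center: float | str | None = "P",
    species: str = "selection",
) -> DensityProfile:
    """Number density of an atom selection along z (nm⁻³ per bin).

    ``selection`` is an index array, or a predicate over atom records (needs
    ``topology``). ``center`` is the bilayer-center convention: an atom name
    whose per-frame mean z defines the origin (default phosphorus), a fixed z
    in nm, or None for the box middle.
    """
    if callable(selection):
        if topology is None:
            raise DomainError("predicate selections need a topology")
        indices = np.array(
            [i for i, a in enumerate(topology.atoms) if selection(a)], dtype=np.intp
        )
    else:
        indices = np.asarray(selection, dtype=np.intp)
    centers_z = _resolve_center(frames, topology, center)
    return _binned_profile(frames, indices, None, bin_width, centers_z, species, "nm^-3")


def electron_density(
    frames: FrameSeries,
    topology: BilayerTopology,
    bin_width: float = 0.1,
    *,
    selection: Sequence[int] | np.ndarray | None = None,
    center: float | str | None = "P",
    species: str = "electrons",
) -> DensityProfile:
    """Electron density along z (e·nm⁻³): atoms weighted by electron count."""
    if selection is None:
        indices = np.arange(topology.n_atoms, dtype=np.intp)
    else:
        indices = np.asarray(selection, dtype=np.intp)
    try:
        weights = np.array([topology.atoms[i].electrons for i in indices], dtype=float)
    except (IndexError, AttributeError) as exc:
        raise TopologyError(f"undefined electron count in selection: {exc}") from exc
    centers_z = _resolve_center(frames, topology, center)
    return _binned_profile(
        frames, indices, weights, bin_width, centers_z, species, "e nm^-3"
    )


def normalize_by_concentration(
    profile: DensityProfile, salt_molarity: float
) -> DensityProfile:
    """Express an ion density as percent of the nominal salt number density.

    A bin exactly at the bulk density given by the salt molarity maps to
    100%; this is the convention used to overlay ion distributions from
    systems at different concentrations.
    """
    if salt_molarity <= 0:
        raise DomainError(f"salt molarity must be > 0, got {salt_molarity}")
    nominal = salt_molarity * NM3_PER_MOLAR  # nm^-3
    return DensityProfile(
        species=profile.species,
        bin_centers=profile.bin_centers,
        density=profile.density / nominal * 100.0,
        n_frames=profile.n_frames,
        bin_volume=profile.bin_volume,
        units="percent",
    )


def form_factor(
    profile: DensityProfile,
    bulk_density: float | None = None,
    q_max: float = 1.0,
    dq: float = 0.001,
    *,
    symmetrize: bool = False,
    bulk_fraction: float = 0.1,
) -> FormFactor:
    """SAXS form factor of an electron-density profile.

    ``bulk_density`` (e·nm⁻³) is subtracted as the solvent background; when
    None it is estimated as the mean over the outermost ``bulk_fraction`` of
    bins on each side. ``symmetrize`` averages ρ(z) with ρ(−z) before
    transforming. Output is normalized by the maximum of |F| over
    q ∈ [0.1, 0.2] Å⁻¹; a zero maximum (featureless contrast) raises a
    normalization error.
    """
    if dq <= 0:
        raise DomainError("dq must be > 0")
    if q_max < 0.2:
        raise DomainError("q_max must reach at least 0.2 1/Å (normalization window)")
    rho = profile.density.astype(float)
    z = profile.bin_centers
    if symmetrize:
        rho = 0.5 * (rho + rho[::-1])
    if bulk_density is None:
        k = max(1, int(round(bulk_fraction * rho.size / 2)))
        bulk_density = float(np.mean(np.concatenate([rho[:k], rho[-k:]])))
    contrast = rho - bulk_density

    # nm, e/nm^3 -> Å, e/Å^3 so that q (1/Å) multiplies z (Å)
    z_ang = z * 10.0
    dz_ang = profile.bin_width * 10.0
    contrast_ang = contrast / 1000.0

    q = np.arange(0.0, q_max + dq / 2.0, dq)
    phase = np.exp(1j * np.outer(q, z_ang))
    raw = np.abs(phase @ contrast_ang) * dz_ang  # e/Å^2

    window = (q >= 0.1) & (q <= 0.2)
    norm = float(raw[window].max())
    if norm == 0.0:
        raise NormalizationError(
            "no form-factor peak: |F| vanishes on the 0.1-0.2 1/Å window"
        )
    return FormFactor(q_grid=q, magnitude=raw / norm, raw_magnitude=raw)
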