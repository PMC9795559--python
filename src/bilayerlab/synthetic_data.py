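"""Synthetic bilayer ensembles with closed-form observables.

Each generator returns (topology, frames, truth) where ``truth`` is the
analytic value of the observable the ensemble is designed to test:

* orientation ensembles — C–H bond vectors drawn i.i.d. per frame from a
  prescribed tilt distribution, with the exact order parameter (fixed tilt:
  P₂(cos θ₀); uniform cone of half-angle θ₀: cos θ₀ (1 + cos θ₀)/2;
  isotropic: 0; mixtures: weighted sums);
* ion slabs — particle z drawn from truncated Gaussians at the interfaces
  plus a uniform bulk component, with the analytic number-density profile;
* Brownian bilayers — 2D lipid center-of-mass random walks wrapped into a
  periodic box, with the input diffusion coefficient;
* Gaussian membranes — point scatterers sampled from a Gaussian
  electron-density profile, with the analytic form factor of the mixture.

Sampling is i.i.d. per frame (no time autocorrelation) — sufficient for the
static observables these ensembles exercise. Every generator takes a
mandatory seed and is bit-reproducible for equal seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from ._elements import electrons_of, mass_of
from .exceptions import DomainError
from .io_core import AtomRecord, BilayerTopology, CHBond, FrameSeries

CH_BOND_LENGTH_NM = 0.109


# ---------------------------------------------------------------------------
# orientation ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationModel:
    """Distribution of C–H bond tilt angles θ against the membrane normal.

    kinds: "fixed" (delta at theta0), "cone" (uniform over solid angle
    within half-angle theta0), "isotropic", "mixture" (weighted components).
    The azimuth is always uniform.
    """

    kind: str
    theta0: float | None = None  # degrees
    components: tuple[tuple[float, "OrientationModel"], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "cone", "isotropic", "mixture"):
            raise DomainError(f"unknown orientation model kind {self.kind!r}")
        if self.kind in ("fixed", "cone"):
            if self.theta0 is None or not (0.0 <= self.theta0 <= 180.0):
                raise DomainError("theta0 must be in [0, 180] degrees")
        if self.kind == "mixture":
            if not self.components:
                raise DomainError("mixture needs components")
            total = sum(w for w, _ in self.components)
            if abs(total - 1.0) > 1e-9:
                raise DomainError(f"mixture weights must sum to 1, got {total}")

    def expected_s(self) -> float:
        """Closed-form order parameter of the model."""
        if self.kind == "fixed":
            c = math.cos(math.radians(self.theta0))
            return 0.5 * (3 * c * c - 1)
        if self.kind == "cone":
            c0 = math.cos(math.radians(self.theta0))
            return 0.5 * c0 * (1 + c0)
        if self.kind == "isotropic":
            return 0.0
        return sum(w * m.expected_s() for w, m in self.components)

    def sample_cos_theta(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, math.cos(math.radians(self.theta0)))
        if self.kind == "cone":
            c0 = math.cos(math.radians(self.theta0))
            return rng.uniform(c0, 1.0, n)
        if self.kind == "isotropic":
            return rng.uniform(-1.0, 1.0, n)
        weights = np.array([w for w, _ in self.components])
        choice = rng.choice(len(self.components), size=n, p=weights)
        out = np.empty(n)
        for i, (_, model) in enumerate(self.components):
            mask = choice == i
            out[mask] = model.sample_cos_theta(rng, int(mask.sum()))
        return out


def gen_orientation_ensemble(
    model: OrientationModel,
    n_lipids: int,
    n_frames: int,
    *,
    bonds: Sequence[tuple[str, str, OrientationModel]] | None = None,
    dt_ps: float = 10.0,
) -> tuple[BilayerTopology, FrameSeries, dict[tuple[str, str], float]]:
    """Generate a bilayer of lipids carrying C–H bonds with prescribed tilts.

    By default each lipid carries one α-carbon R bond following ``model``;
    ``bonds`` overrides with a list of (segment_label, stereo_label, model)
    so forking and ΔS scenarios can be built. Each lipid also carries a
    phosphorus anchor so leaflet assignment works. Truth maps
    (segment, stereo) to the exact S_CH.
    """
    if n_lipids < 1 or n_frames < 1:
        raise DomainError("counts must be >= 1")
    if bonds is None:
        bonds = [("α", "R", model)]
    rng = np.random.default_rng(model.seed)

    grid = int(np.ceil(np.sqrt(n_lipids)))
    spacing = 0.8  # nm
    box_l = max(4.0, grid * spacing + 2.0)
    box = np.array([box_l, box_l, 8.0])

    atoms: list[AtomRecord] = []
    ch_bonds: list[CHBond] = []
    base_xy = []
    leaflet: dict[int, str] = {}
    for lid in range(n_lipids):
        gx, gy = divmod(lid, grid)
        x, y = 1.0 + gx * spacing, 1.0 + gy * spacing
        upper = lid < (n_lipids + 1) // 2
        z0 = box[2] / 2 + (1.0 if upper else -1.0)
        leaflet[lid] = "upper" if upper else "lower"
        atoms.append(AtomRecord(lid, "P", "P", mass_of("P"), electrons_of("P")))
        base_xy.append((x, y, z0))
        for seg, stereo, _ in bonds:
            c_idx = len(atoms)
            atoms.append(AtomRecord(lid, "C", "C", mass_of("C"), electrons_of("C")))
            atoms.append(
                AtomRecord(lid, "H", "H", mass_of("H"), electrons_of("H"), stereo)
            )
            ch_bonds.append(CHBond(c_idx, c_idx + 1, seg, stereo))

    n_atoms = len(atoms)
    coords = np.zeros((n_frames, n_atoms, 3))
    # static positions for P and C atoms
    static = np.zeros((n_atoms, 3))
    atom_ptr = 0
    for lid in range(n_lipids):
        x, y, z0 = base_xy[lid]
        static[atom_ptr] = (x, y, z0)  # P
        atom_ptr += 1
        for j in range(len(bonds)):
            static[atom_ptr] = (x, y, z0 + 0.1 * (j + 1))  # C
            static[atom_ptr + 1] = static[atom_ptr]  # H placeholder
            atom_ptr += 2
    coords[:] = static[None, :, :]

    # per-frame bond vectors, one stream per bond class for reproducibility
    truth: dict[tuple[str, str], float] = {}
    for j, (seg, stereo, bmodel) in enumerate(bonds):
        truth[(seg, stereo)] = bmodel.expected_s()
        cos_t = bmodel.sample_cos_theta(rng, n_frames * n_lipids).reshape(
            n_frames, n_lipids
        )
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
        phi = rng.uniform(0.0, 2 * np.pi, (n_frames, n_lipids))
        vec = (
            np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1)
            * CH_BOND_LENGTH_NM
        )
        for lid in range(n_lipids):
            # atoms per lipid: P, then (C, H) per bond
            c_idx = lid * (1 + 2 * len(bonds)) + 1 + 2 * j
            coords[:, c_idx + 1, :] = coords[:, c_idx, :] + vec[:, lid, :]

    topo = BilayerTopology(
        atoms=atoms, ch_bonds=ch_bonds, leaflet=leaflet, n_lipids=n_lipids
    )
    frames = FrameSeries(
        times=np.arange(n_frames) * dt_ps,
        coords=coords,
        box=np.tile(box, (n_frames, 1)),
    )
    return topo, frames, truth


# ---------------------------------------------------------------------------
# ion slabs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayeringModel:
    """Ion/water z-distribution: Gaussian surface peaks + uniform bulk.

    ``peaks`` holds (z_center nm relative to the bilayer center, sigma nm,
    weight); weights plus ``bulk_fraction`` must sum to 1. Gaussians are
    truncated (not reflected) at the box edges and renormalized
    analytically, so the truth density stays closed-form.
    """

    peaks: tuple[tuple[float, float, float], ...]
    bulk_fraction: float
    n_particles: int
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(w for _, _, w in self.peaks) + self.bulk_fraction
        if abs(total - 1.0) > 1e-9:
            raise DomainError(f"peak weights + bulk_fraction must sum to 1, got {total}")
        if any(s <= 0 for _, s, _ in self.peaks):
            raise DomainError("peak sigma must be > 0")
        if not (0.0 <= self.bulk_fraction <= 1.0):
            raise DomainError("bulk_fraction must be in [0, 1]")
        if self.n_particles < 1:
            raise DomainError("n_particles must be >= 1")


def _truncnorm_mass(mu: float, sigma: float, a: float, b: float) -> float:
    return float(norm.cdf((b - mu) / sigma) - norm.cdf((a - mu) / sigma))


def gen_ion_slab(
    model: LayeringModel,
    box: tuple[float, float, float],
    n_frames: int,
    *,
    element: str = "Na",
    dt_ps: float = 10.0,
) -> tuple[BilayerTopology, FrameSeries, Callable[[np.ndarray], np.ndarray]]:
    """Sample an ion slab; z from the layering mixture, xy uniform.

    Coordinates are centered: z ∈ [−Lz/2, Lz/2). The returned truth is the
    analytic number density n(z) in nm⁻³ (callable on z arrays). Particles
    are re-drawn independently every frame.
    """
    from scipy.stats import truncnorm

    lx, ly, lz = box
    a, b = -lz / 2.0, lz / 2.0
    for z0, sigma, w in model.peaks:
        if w > 0 and not (a < z0 < b):
            raise DomainError(f"peak at z={z0} outside box [-{lz / 2}, {lz / 2}]")
    rng = np.random.default_rng(model.seed)
    n = model.n_particles

    weights = np.array([w for _, _, w in model.peaks] + [model.bulk_fraction])
    comps = len(weights)
    coords = np.empty((n_frames, n, 3))
    for f in range(n_frames):
        coords[f, :, 0] = rng.uniform(0.0, lx, n)
        coords[f, :, 1] = rng.uniform(0.0, ly, n)
        which = rng.choice(comps, size=n, p=weights)
        z = np.empty(n)
        for i, (z0, sigma, _) in enumerate(model.peaks):
            mask = which == i
            if mask.any():
                lo, hi = (a - z0) / sigma, (b - z0) / sigma
                z[mask] = truncnorm.rvs(
                    lo, hi, loc=z0, scale=sigma, size=int(mask.sum()), random_state=rng
                )
        mask = which == comps - 1
        if mask.any():
            z[mask] = rng.uniform(a, b, int(mask.sum()))
        coords[f, :, 2] = z

    atoms = [
        AtomRecord(-1, element.upper(), element, mass_of(element), electrons_of(element))
        for _ in range(n)
    ]
    topo = BilayerTopology(atoms=atoms)
    frames = FrameSeries(
        times=np.arange(n_frames) * dt_ps,
        coords=coords,
        box=np.tile(np.array(box), (n_frames, 1)),
    )

    peaks = model.peaks
    bulk = model.bulk_fraction
    area = lx * ly

    def truth_density(z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        pdf = np.full(z.shape, bulk / lz)
        for z0, sigma, w in peaks:
            mass = _truncnorm_mass(z0, sigma, a, b)
            inside = (z >= a) & (z <= b)
            pdf = pdf + np.where(
                inside, w * norm.pdf(z, loc=z0, scale=sigma) / mass, 0.0
            )
        return n * pdf / area

    return topo, frames, truth_density


# ---------------------------------------------------------------------------
# Brownian bilayer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BrownianModel:
    """2D Brownian lipid motion in a periodic box.

    d_true is the lateral diffusion coefficient in m²/s; drift is a common
    xy velocity in nm/ps added to every lipid.
    """

    d_true: float
    n_lipids: int = 200
    n_frames: int = 10_000
    dt: float = 100.0  # ps between saved frames
    box: tuple[float, float, float] = (8.0, 8.0, 8.0)
    drift: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_true < 0:
            raise DomainError("d_true must be >= 0")
        if self.dt <= 0:
            raise DomainError("dt must be > 0")


M2S_TO_NM2PS = 1e6  # 1 m^2/s = 1e6 nm^2/ps


def gen_brownian_bilayer(
    model: BrownianModel,
) -> tuple[BilayerTopology, FrameSeries, float]:
    """Wrapped 2D random walks of single-site lipids; truth is d_true.

    Per-axis step standard deviation is sqrt(2·D·dt). Half the lipids sit
    in each leaflet (z = box/2 ± 1 nm); each lipid is a single phosphorus-
    anchored pseudo-atom of lipid-like mass, so center-of-mass extraction
    and unwrapping are exercised end to end.
    """
    rng = np.random.default_rng(model.seed)
    n, f = model.n_lipids, model.n_frames
    lx, ly, lz = model.box
    d_nm = model.d_true * M2S_TO_NM2PS  # nm^2/ps
    step_sd = math.sqrt(2.0 * d_nm * model.dt)

    start = np.column_stack([rng.uniform(0, lx, n), rng.uniform(0, ly, n)])
    steps = rng.normal(0.0, step_sd, size=(f - 1, n, 2)) if f > 1 else np.zeros((0, n, 2))
    xy = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)], axis=0)
    drift = np.asarray(model.drift)
    if np.any(drift != 0.0):
        t = (np.arange(f) * model.dt)[:, None, None]
        xy = xy + drift[None, None, :] * t

    coords = np.empty((f, n, 3))
    coords[:, :, 0] = np.mod(xy[:, :, 0], lx)
    coords[:, :, 1] = np.mod(xy[:, :, 1], ly)
    upper = np.arange(n) < (n + 1) // 2
    coords[:, :, 2] = np.where(upper, lz / 2 + 1.0, lz / 2 - 1.0)[None, :]

    atoms = [
        AtomRecord(lid, "P", "P", 720.0, electrons_of("P")) for lid in range(n)
    ]
    leaflet = {lid: ("upper" if upper[lid] else "lower") for lid in range(n)}
    topo = BilayerTopology(atoms=atoms, leaflet=leaflet, n_lipids=n)
    frames = FrameSeries(
        times=np.arange(f) * model.dt,
        coords=coords,
        box=np.tile(np.array(model.box), (f, 1)),
    )
    return topo, frames, model.d_true


# ---------------------------------------------------------------------------
# Gaussian membrane (form-factor oracle)
# ---------------------------------------------------------------------------

def gen_gaussian_membrane(
    peaks: Sequence[tuple[float, float, float]],
    box: tuple[float, float, float],
    n_particles: int,
    seed: int,
    *,
    electrons_per_particle: int = 8,
    bulk_fraction: float = 0.0,
    n_frames: int = 1,
) -> tuple[BilayerTopology, FrameSeries, Callable[[np.ndarray], np.ndarray]]:
    """Point-scatterer slab with an analytic Gaussian electron-density profile.

    ``peaks`` are (z_center nm, sigma nm, weight) relative to the bilayer
    center; a nonzero ``bulk_fraction`` adds a uniform (contrast-free)
    component. Truth is the unnormalized analytic |F(q)| of the Gaussian
    mixture (q in Å⁻¹), valid when each peak sits several sigma inside the
    box so truncation is negligible.
    """
    model = LayeringModel(
        peaks=tuple(peaks),
        bulk_fraction=bulk_fraction,
        n_particles=n_particles,
        seed=seed,
    )
    topo, frames, _ = gen_ion_slab(model, box, n_frames, element="O")
    atoms = [
        AtomRecord(-1, "O", "O", mass_of("O"), electrons_per_particle)
        for _ in range(n_particles)
    ]
    topo = BilayerTopology(atoms=atoms)

    peaks = tuple(peaks)

    def truth_formfactor(q_inv_ang: np.ndarray) -> np.ndarray:
        """|F|(q) up to a global scale: |Σ w_j exp(−q²σ_j²/2) exp(i q z_j)|."""
        q = np.asarray(q_inv_ang, dtype=float)
        f = np.zeros(q.shape, dtype=complex)
        for z0, sigma, w in peaks:
            z0_a, s_a = z0 * 10.0, sigma * 10.0
            f = f + w * s_a * math.sqrt(2 * math.pi) * np.exp(
                -0.5 * (q * s_a) ** 2
            ) * np.exp(1j * q * z0_a)
        return np.abs(f)

    return topo, frames, truth_formfactor
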