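"""Shared fixtures: small synthetic ensembles with known ground truth."""

import numpy as np
import pytest

from bilayerlab import (
    AtomRecord,
    BilayerTopology,
    CHBond,
    FrameSeries,
    OrientationModel,
    gen_orientation_ensemble,
)


def make_frames(coords, box=(5.0, 5.0, 5.0), dt=10.0):
    """FrameSeries from an (F, N, 3) array and a constant box."""
    coords = np.asarray(coords, dtype=float)
    f = coords.shape[0]
    return FrameSeries(
        times=np.arange(f) * dt,
        coords=coords,
        box=np.tile(np.asarray(box, dtype=float), (f, 1)),
    )


def tilted_bond_frames(thetas_deg, phi_deg=0.0):
    """One C-H bond whose tilt angle per frame is prescribed exactly.

    Returns (topology, frames) with atoms [C, H]; the bond vector of frame i
    has polar angle thetas_deg[i] against +z.
    """
    thetas = np.radians(np.asarray(thetas_deg, dtype=float))
    phi = np.radians(phi_deg)
    f = thetas.size
    coords = np.zeros((f, 2, 3))
    coords[:, 0] = (2.5, 2.5, 2.5)
    length = 0.109
    coords[:, 1, 0] = coords[:, 0, 0] + length * np.sin(thetas) * np.cos(phi)
    coords[:, 1, 1] = coords[:, 0, 1] + length * np.sin(thetas) * np.sin(phi)
    coords[:, 1, 2] = coords[:, 0, 2] + length * np.cos(thetas)
    atoms = [
        AtomRecord(0, "C11", "C", 12.011, 6),
        AtomRecord(0, "H11A", "H", 1.008, 1, "R"),
    ]
    topo = BilayerTopology(
        atoms=atoms,
        ch_bonds=[CHBond(0, 1, "α", "R")],
        leaflet={0: "upper"},
        n_lipids=1,
    )
    return topo, make_frames(coords)


@pytest.fixture(scope="session")
def cone60_ensemble():
    """200 lipids x 2000 frames from a 60° uniform cone; exact S = 0.375."""
    model = OrientationModel(kind="cone", theta0=60.0, seed=601)
    return gen_orientation_ensemble(model, 200, 2000)


@pytest.fixture(scope="session")
def isotropic_ensemble():
    """200 lipids x 2000 frames of isotropic bond orientations; exact S = 0."""
    model = OrientationModel(kind="isotropic", seed=77)
    return gen_orientation_ensemble(model, 200, 2000)
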