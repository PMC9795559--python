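"""Signed C–H bond order parameters and derived observables.

The order parameter of a C–H bond is

    S_CH = < (3 cos²θ − 1) / 2 >

with θ the angle between the carbon→hydrogen vector and the membrane normal
(+z) and the average taken over sampled conformations. Averaging follows the
per-lipid scheme used in NMR-oriented trajectory analysis: S_CH is first
time-averaged for each lipid separately, then the mean and standard error of
the mean (SEM) are taken over lipids, which treats lipids — not frames — as
the independent samples.

S_CH is reported signed; comparing against magnitude-only ²H NMR data is a
caller concern. θ uses the carbon→hydrogen direction; the antiparallel
convention would map θ → 180°−θ but leaves S_CH unchanged (P₂ is even).
Frames are weighted equally in the time average; unevenly spaced frames are
averaged unweighted with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateGeometryError, DomainError
from .io_core import BilayerTopology, CHBond, FrameSeries, segment_sort_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ChOrderParameter:
    """Lipid-ensemble order parameter of one C–H bond class."""

    segment_label: str
    stereo_label: str
    s_mean: float
    sem: float
    n_lipids: int

    def __post_init__(self) -> None:
        if not (-0.5 - 1e-12 <= self.s_mean <= 1.0 + 1e-12):
            raise DomainError(f"s_mean {self.s_mean} outside [-0.5, 1]")
        if not (self.sem >= 0 or math.isnan(self.sem)):
            raise DomainError("sem must be >= 0 (or NaN when undefined)")
        if self.n_lipids < 1:
            raise DomainError("n_lipids must be >= 1")


@dataclass(frozen=True)
class ThetaDistribution:
    """Histogram of the C–H tilt angle θ ∈ [0°, 180°], averaged over lipids."""

    bin_edges: np.ndarray  # degrees
    probability: np.ndarray  # per bin, sums to 1
    sem: np.ndarray  # per bin, over lipids

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.probability)) - 1.0) > 1e-9:
            raise DomainError("bin probabilities must sum to 1")
        if np.any(self.probability < 0):
            raise DomainError("negative bin probability")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class DeltaS:
    """Order-parameter change relative to a salt-free R/S-averaged baseline."""

    segment_label: str
    concentration: float | None  # molarity; None when not applicable
    delta: float
    sem: float


def _cos_theta(frames: FrameSeries, bond: CHBond) -> np.ndarray:
    """cos θ of the C→H vector against +z, per frame."""
    vec = frames.coords[:, bond.hydrogen, :] - frames.coords[:, bond.carbon, :]
    norm = np.linalg.norm(vec, axis=1)
    bad = np.nonzero(norm == 0.0)[0]
    if bad.size:
        raise DegenerateGeometryError(
            f"zero-length C-H vector at frame {int(bad[0])} "
            f"(atoms {bond.carbon}-{bond.hydrogen})"
        )
    return vec[:, 2] / norm


def sch_per_lipid(
    frames: FrameSeries,
    bond: CHBond,
    lipid_id: int | None = None,
    topology: BilayerTopology | None = None,
) -> float:
    """Time-averaged S_CH of a single C–H bond (one lipid).

    When a topology is supplied the bond atoms are checked to belong to
    ``lipid_id``. Raises a degeneracy error naming the first frame with a
    zero-length bond vector.
    """
    if frames.n_frames < 1:
        raise DomainError("need at least one frame")
    if topology is not None and lipid_id is not None:
        for idx in (bond.carbon, bond.hydrogen):
            if topology.atoms[idx].lipid_id != lipid_id:
                raise DomainError(
                    f"bond atom {idx} belongs to lipid {topology.atoms[idx].lipid_id}, "
                    f"not {lipid_id}"
                )
    if frames.n_frames > 1:
        dt = np.diff(frames.times)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            logger.warning("unevenly spaced frames; averaging unweighted")
    c = _cos_theta(frames, bond)
    return float(np.mean(1.5 * c * c - 0.5))


def sch_ensemble(
    per_lipid_values: Sequence[float], segment_label: str, stereo_label: str
) -> ChOrderParameter:
    """Mean and SEM of per-lipid S_CH values (lipids as independent samples).

    A single lipid yields a NaN SEM (undefined) rather than an error.
    """
    values = np.asarray(per_lipid_values, dtype=float)
    if values.size < 1:
        raise DomainError("need at least one per-lipid value")
    if values.size == 1:
        sem = float("nan")
    else:
        sem = float(np.std(values, ddof=1) / np.sqrt(values.size))
    return ChOrderParameter(
        segment_label=segment_label,
        stereo_label=stereo_label,
        s_mean=float(values.mean()),
        sem=sem,
        n_lipids=int(values.size),
    )


def compute_order_parameters(
    frames: FrameSeries, topology: BilayerTopology
) -> list[ChOrderParameter]:
    """Per-lipid-then-ensemble S_CH for every (segment, stereo) bond class.

    Bonds sharing segment and stereo labels across lipids form one class;
    each lipid contributes the time average over its own bond(s) of that
    class, and the ensemble statistics are taken across lipids.
    """
    groups: dict[tuple[str, str], dict[int, list[float]]] = {}
    for bond in topology.ch_bonds:
        lid = topology.lipid_of_bond(bond)
        val = sch_per_lipid(frames, bond)
        groups.setdefault((bond.segment_label, bond.stereo_label), {}).setdefault(
            lid, []
        ).append(val)
    out: list[ChOrderParameter] = []
    for (seg, st), per_lipid in sorted(
        groups.items(), key=lambda kv: (segment_sort_key(kv[0][0]), kv[0][1])
    ):
        values = [float(np.mean(v)) for _, v in sorted(per_lipid.items())]
        out.append(sch_ensemble(values, seg, st))
    return out


def order_parameters_frame(records: Sequence[ChOrderParameter], n_frames: int | None = None) -> pd.DataFrame:
    """Tabulate order-parameter records in canonical segment order."""
    df = pd.DataFrame(
        {
            "segment_label": [r.segment_label for r in records],
            "stereo_label": [r.stereo_label for r in records],
            "s_mean": [r.s_mean for r in records],
            "sem": [r.sem for r in records],
            "n_lipids": [r.n_lipids for r in records],
        }
    )
    if n_frames is not None:
        df["n_frames"] = n_frames
    key = df["segment_label"].map(segment_sort_key)
    return df.assign(_k=key).sort_values(["_k", "stereo_label"]).drop(columns="_k").reset_index(drop=True)


def theta_distribution(
    frames: FrameSeries,
    topology: BilayerTopology,
    bond_set: Sequence[CHBond] | None = None,
    lipid_subset: Sequence[int] | None = None,
    bins: int = 36,
) -> ThetaDistribution:
    """θ-angle histogram of a bond set, averaged over a lipid subset.

    Each lipid contributes its own normalized histogram over [0°, 180°]
    (pooling all selected bonds and frames of that lipid); the returned
    probability and SEM are the per-bin mean and standard error across
    lipids.
    """
    if bins < 2:
        raise DomainError("bins must be >= 2")
    bonds = list(bond_set) if bond_set is not None else list(topology.ch_bonds)
    if lipid_subset is None:
        lipid_subset = sorted({topology.lipid_of_bond(b) for b in bonds})
    lipid_subset = list(lipid_subset)
    if not lipid_subset or not bonds:
        raise DomainError("empty lipid subset or bond set")
    edges = np.linspace(0.0, 180.0, bins + 1)
    per_lipid_hists = []
    for lid in lipid_subset:
        thetas = []
        for bond in bonds:
            if topology.lipid_of_bond(bond) != lid:
                continue
            c = np.clip(_cos_theta(frames, bond), -1.0, 1.0)
            thetas.append(np.degrees(np.arccos(c)))
        if not thetas:
            raise DomainError(f"lipid {lid} has no bonds in the bond set")
        th = np.concatenate(thetas)
        hist, _ = np.histogram(th, bins=edges)
        per_lipid_hists.append(hist / hist.sum())
    h = np.array(per_lipid_hists)
    prob = h.mean(axis=0)
    prob = prob / prob.sum()  # guard rounding so the invariant holds exactly
    sem = (
        h.std(axis=0, ddof=1) / np.sqrt(h.shape[0])
        if h.shape[0] > 1
        else np.full(bins, np.nan)
    )
    return ThetaDistribution(bin_edges=edges, probability=prob, sem=sem)


def detect_forking(
    r: ChOrderParameter, s: ChOrderParameter, k_sigma: float = 2.0
) -> tuple[float, bool]:
    """Forking magnitude |S_R − S_S| and its significance.

    Forking — unequal order parameters for the two hydrogens bonded to the
    same carbon — is called significant when the magnitude exceeds
    ``k_sigma`` combined standard errors (quadrature). Symmetric in R/S.
    """
    if r.segment_label != s.segment_label:
        raise DomainError(
            f"segment mismatch: {r.segment_label!r} vs {s.segment_label!r}"
        )
    if {r.stereo_label, s.stereo_label} != {"R", "S"}:
        raise DomainError("detect_forking needs one R and one S record")
    magnitude = abs(r.s_mean - s.s_mean)
    threshold = k_sigma * math.hypot(r.sem, s.sem)
    significant = bool(magnitude > threshold)
    return magnitude, significant


def delta_sch(
    record_at_c: ChOrderParameter,
    baseline_r: ChOrderParameter,
    baseline_s: ChOrderParameter,
    concentration: float | None = None,
) -> DeltaS:
    """Electrometer response ΔS_CH against an R/S-averaged salt-free baseline.

    ΔS = S(c) − (S_R⁰ + S_S⁰)/2, with the SEM propagated in quadrature
    (the baseline halves enter with factor ½).
    """
    for rec in (baseline_r, baseline_s):
        if rec.segment_label != record_at_c.segment_label:
            raise DomainError(
                f"segment mismatch: {rec.segment_label!r} vs {record_at_c.segment_label!r}"
            )
    baseline = 0.5 * (baseline_r.s_mean + baseline_s.s_mean)
    delta = record_at_c.s_mean - baseline
    sem = math.sqrt(
        record_at_c.sem**2 + 0.25 * baseline_r.sem**2 + 0.25 * baseline_s.sem**2
    )
    return DeltaS(
        segment_label=record_at_c.segment_label,
        concentration=concentration,
        delta=delta,
        sem=sem,
    )
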