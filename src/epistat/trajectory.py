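"""Trajectory-level stability metrics for protein-protein complexes.

Implements the measurements used to judge whether a simulated antigen-antibody
complex stays in its crystallographic pose: least-squares (Kabsch)
superposition, C-alpha RMSD against a reference structure, ligand-RMSD
(L-RMSD: superpose on the antigen C-alphas, measure the RMSD of the antibody
C-alphas without re-fitting), per-frame charged-atom distance series,
contact-occupancy fractions with a burn-in window, and replica aggregation.

Trajectories are multi-model PDB natively; DCD/XTC are accepted through
MDAnalysis when it is installed.  Frames are assumed pre-imaged with the
complex whole — no minimum-image correction is applied, and a loud warning is
emitted if any atom jumps more than 20 A between consecutive frames, which
usually indicates an un-imaged periodic trajectory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    CapabilityError,
    DegenerateGeometryError,
    EmptyWindowError,
    SelectionError,
    UsageError,
)
from .structures import ContactDefinition, StructureModel, parse_pdb

__all__ = [
    "Trajectory",
    "SuperpositionResult",
    "OccupancySummary",
    "ReplicaSummary",
    "LRMSDResult",
    "kabsch_superpose",
    "rmsd_series",
    "lrmsd_series",
    "distance_series",
    "contact_occupancy",
    "replica_summary",
    "occupancy_summary",
    "load_trajectory_pdb",
    "load_trajectory",
]

#: Default snapshot spacing in ns (one saved frame every 10 ps).
DEFAULT_DT_NS = 0.01

#: Inter-frame displacement (A) beyond which an imaging problem is suspected.
JUMP_WARNING_A = 20.0


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered coordinate frames bound to one topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in A; ``times`` is in ns and
    strictly increasing.  The topology provides atom identities and the flat
    atom order the frame arrays follow.
    """

    topology: StructureModel
    frames: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise SelectionError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise SelectionError(
                f"frames have {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise SelectionError("times and frames must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise SelectionError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation and the minimized RMSD (A)."""

    rotation: np.ndarray     # 3x3, det = +1
    translation: np.ndarray  # 3-vector, A
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid motion to an (n, 3) coordinate array."""
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class ReplicaSummary:
    """Across-replica mean with sample sd (n-1) and standard error sd/sqrt(n)."""

    mean: float
    sd: float
    se: float
    n: int
    spread_defined: bool


@dataclass
class OccupancySummary:
    """Per-contact occupancy across replicas (fractions of post-burn-in frames)."""

    contact_label: str
    per_replica_fraction: list[float]
    mean: float
    sd: float
    se: float
    burn_in_ns: float
    spread_defined: bool = True


@dataclass
class LRMSDResult:
    """L-RMSD series plus its across-frame average and standard deviation."""

    series: np.ndarray  # (n_frames, 2): time_ns, lrmsd_A
    mean: float
    sd: float


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation R and translation t minimizing the (weighted)
    RMSD of ``R @ x + t`` against the reference.  Reflections are excluded by
    sign-correcting the smallest singular vector, so det(R) = +1 always.

    Raises :class:`DegenerateGeometryError` for fewer than 3 points or
    (near-)collinear configurations, where the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SelectionError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise UsageError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ mobile
    cr = w @ reference
    a = mobile - cm
    b = reference - cr
    h = (a * w[:, None]).T @ b
    u, s, vt = np.linalg.svd(h)
    scale = float(np.abs(s[0])) if s[0] > 0 else 1.0
    if s[1] <= 1e-10 * scale:
        raise DegenerateGeometryError("points are collinear; rotation not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    fitted = a @ rotation.T
    rmsd = math.sqrt(float(np.sum(w[:, None] * (fitted - b) ** 2)))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


# --------------------------------------------------------------------------
# per-frame metrics
# --------------------------------------------------------------------------

def _plain_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    return math.sqrt(float(np.mean(np.sum((x - y) ** 2, axis=1))))


def _reference_coords(reference: StructureModel, n_atoms: int) -> np.ndarray:
    coords = reference.coords()
    if coords.shape[0] != n_atoms:
        raise SelectionError(
            f"reference has {coords.shape[0]} atoms, trajectory topology has {n_atoms}"
        )
    return coords


def rmsd_series(traj: Trajectory, measure_mask: np.ndarray, reference: StructureModel,
                fit_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-frame C-alpha RMSD against a reference after least-squares fitting.

    Each frame is superposed onto the reference using ``fit_mask`` (defaults to
    the measured atoms) and the RMSD is evaluated over ``measure_mask``.
    Returns an (n_frames, 2) array of (time_ns, rmsd_A).
    """
    measure_mask = np.asarray(measure_mask, dtype=int)
    fit = measure_mask if fit_mask is None else np.asarray(fit_mask, dtype=int)
    if len(measure_mask) < 1 or len(fit) < 3:
        raise SelectionError("masks must select >= 3 atoms for fitting")
    ref = _reference_coords(reference, traj.frames.shape[1])
    out = np.empty((traj.n_frames, 2))
    for i, frame in enumerate(traj.frames):
        sup = kabsch_superpose(frame[fit], ref[fit])
        out[i] = (traj.times[i], _plain_rmsd(sup.apply(frame[measure_mask]),
                                             ref[measure_mask]))
    return out


def lrmsd_series(traj: Trajectory, antigen_fit_mask: np.ndarray,
                 antibody_measure_mask: np.ndarray,
                 reference: StructureModel) -> LRMSDResult:
    """Ligand-RMSD: fit each frame on the antigen C-alphas, then measure the
    antibody C-alpha RMSD without re-fitting.

    A whole-complex rigid motion gives zero; relative reorientation or drift of
    the antibody against the antigen shows up directly, which makes the metric
    a complex-stability readout.  Returns the series with its across-frame mean
    and standard deviation.
    """
    fit = np.asarray(antigen_fit_mask, dtype=int)
    measure = np.asarray(antibody_measure_mask, dtype=int)
    if np.intersect1d(fit, measure).size:
        raise UsageError("fit and measure selections must be disjoint for L-RMSD")
    series = rmsd_series(traj, measure, reference, fit_mask=fit)
    values = series[:, 1]
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return LRMSDResult(series=series, mean=float(values.mean()), sd=sd)


def distance_series(traj: Trajectory, contact: ContactDefinition) -> np.ndarray:
    """Per-frame distance (A) between the contact's two named atoms.

    Returns an (n_frames, 2) array of (time_ns, distance_A).
    """
    index = traj.topology.flat_index()
    ka = traj.topology.resolve(contact.res_a)
    kb = traj.topology.resolve(contact.res_b)
    ia = index[(ka.chain_id, ka.res_seq, ka.i_code, contact.atom_a)] \
        if (ka.chain_id, ka.res_seq, ka.i_code, contact.atom_a) in index else None
    if ia is None:
        raise SelectionError(f"atom {contact.atom_a!r} of {ka} not in topology")
    key_b = (kb.chain_id, kb.res_seq, kb.i_code, contact.atom_b)
    if key_b not in index:
        raise SelectionError(f"atom {contact.atom_b!r} of {kb} not in topology")
    ib = index[key_b]
    d = np.linalg.norm(traj.frames[:, ia, :] - traj.frames[:, ib, :], axis=1)
    return np.column_stack([traj.times, d])


def contact_occupancy(series: np.ndarray, threshold: float, burn_in: float = 0.0) -> float:
    """Fraction of post-burn-in frames with distance <= threshold.

    ``series`` is an (n, 2) array of (time_ns, distance_A); frames with
    time >= ``burn_in`` (ns) are counted.
    """
    if threshold <= 0:
        raise UsageError("threshold must be positive")
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 2 or len(series) == 0:
        raise UsageError("series must be a non-empty (n, 2) array of (time, distance)")
    keep = series[:, 0] >= burn_in
    if not keep.any():
        raise EmptyWindowError(
            f"no frames at or after burn-in of {burn_in} ns "
            f"(last frame at {series[-1, 0]} ns)"
        )
    return float(np.mean(series[keep, 1] <= threshold))


def default_burn_in(traj: Trajectory, fraction: float = 0.2) -> float:
    """Burn-in as the first ``fraction`` of the trajectory span (default 20%)."""
    return float(traj.times[0] + fraction * (traj.times[-1] - traj.times[0]))


# --------------------------------------------------------------------------
# replica statistics
# --------------------------------------------------------------------------

def replica_summary(values: Sequence[float]) -> ReplicaSummary:
    """Mean, sample sd (n-1 denominator) and standard error across replicas.

    With a single replica the mean is returned with NaN spread and
    ``spread_defined`` False, rather than a silent zero.
    """
    arr = np.sort(np.asarray(list(values), dtype=float))  # order-independent sums
    if arr.size == 0:
        raise UsageError("need at least one replica value")
    mean = float(arr.mean())
    if arr.size < 2:
        return ReplicaSummary(mean=mean, sd=math.nan, se=math.nan, n=1,
                              spread_defined=False)
    sd = float(arr.std(ddof=1))
    return ReplicaSummary(mean=mean, sd=sd, se=sd / math.sqrt(arr.size),
                          n=int(arr.size), spread_defined=True)


def occupancy_summary(contact_label: str, fractions: Sequence[float],
                      burn_in_ns: float) -> OccupancySummary:
    """Bundle per-replica occupancy fractions into an across-replica summary."""
    fracs = [float(f) for f in fractions]
    if any(not 0.0 <= f <= 1.0 for f in fracs):
        raise UsageError("occupancy fractions must lie in [0, 1]")
    stats = replica_summary(fracs)
    return OccupancySummary(
        contact_label=contact_label, per_replica_fraction=fracs,
        mean=stats.mean, sd=stats.sd, se=stats.se,
        burn_in_ns=float(burn_in_ns), spread_defined=stats.spread_defined,
    )


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

def _warn_on_jumps(frames: np.ndarray) -> None:
    if len(frames) < 2:
        return
    jumps = np.linalg.norm(np.diff(frames, axis=0), axis=2)
    worst = float(jumps.max())
    if worst > JUMP_WARNING_A:
        warnings.warn(
            f"inter-frame atom jump of {worst:.1f} A exceeds {JUMP_WARNING_A} A: "
            "the trajectory may not be re-imaged with the complex whole",
            stacklevel=3,
        )


def load_trajectory_pdb(source, dt_ns: float = DEFAULT_DT_NS,
                        times: Sequence[float] | None = None) -> Trajectory:
    """Load a multi-model PDB as a trajectory.

    PDB carries no time information, so frame times default to
    ``frame_index * dt_ns`` (10 ps spacing) unless explicit times are given.
    """
    models = parse_pdb(source)
    topology = models[0]
    n_atoms = topology.n_atoms
    for m in models[1:]:
        if m.n_atoms != n_atoms:
            raise SelectionError(
                f"model {m.model_index} has {m.n_atoms} atoms, expected {n_atoms}"
            )
    frames = np.stack([m.coords() for m in models])
    if times is None:
        times = np.arange(len(models)) * dt_ns
    traj = Trajectory(topology=topology, frames=frames, times=np.asarray(times, float))
    _warn_on_jumps(traj.frames)
    return traj


def load_trajectory(path, topology_path=None, dt_ns: float = DEFAULT_DT_NS) -> Trajectory:
    """Load a trajectory by extension: ``.pdb`` natively, ``.dcd``/``.xtc``/``.trr``
    through MDAnalysis when available."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return load_trajectory_pdb(path, dt_ns=dt_ns)
    if suffix in {".dcd", ".xtc", ".trr"}:
        if topology_path is None:
            raise UsageError(f"a PDB topology is required to read {suffix} trajectories")
        try:
            import MDAnalysis as mda
        except ImportError as exc:  # pragma: no cover - depends on install
            raise CapabilityError(
                f"reading {suffix} trajectories requires MDAnalysis, which is not "
                "installed; convert to multi-model PDB or install the "
                "'traj-readers' extra"
            ) from exc
        topology = parse_pdb(topology_path)[0]
        universe = mda.Universe(str(topology_path), str(path))
        heavy = universe.select_atoms("not (name H* or type H)")
        frames = np.array([heavy.positions.copy() for _ in universe.trajectory],
                          dtype=float)
        if frames.shape[1] != topology.n_atoms:
            raise SelectionError(
                f"trajectory heavy-atom count {frames.shape[1]} does not match "
                f"topology ({topology.n_atoms})"
            )
        times = np.arange(len(frames)) * dt_ns
        traj = Trajectory(topology=topology, frames=frames, times=times)
        _warn_on_jumps(traj.frames)
        return traj
    raise UsageError(f"unsupported trajectory format: {suffix!r}")
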