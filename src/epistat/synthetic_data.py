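"""Seeded synthetic-data generators with exact ground truth.

Every input the analysis stages consume can be generated here: toy two-chain
complexes with planted charged-pair contacts, harmonically fluctuating
trajectories with prescribed per-contact occupancies and optional inter-chain
drift (a dissociating complex), 1:1 Langmuir sensorgram panels at the
standard six two-fold dilutions, KD(T) series from stated enthalpy/entropy,
single-peak DSC thermograms, and uniform nonbonded-parameter tables for toy
systems.  All generators are pure functions of their seed and return
machine-readable ground truth alongside the data, so parameter-recovery tests
can assert against construction rather than against another estimate.

Toy complexes use idealized residue geometry (backbone N/CA/C plus the
charged-group atoms) and are deliberately non-physical: contact toggling
follows independent Bernoulli schedules rather than any potential, so
occupancy ground truth is exact by construction, not emergent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding_kinetics import PhaseSchedule, R_GAS_KJ, Sensorgram, simulate_sensorgram
from .energetics import NonbondedParams
from .errors import GenerationError, UsageError
from .structures import (
    DEFAULT_CHARGED_GROUPS,
    AtomRecord,
    ContactDefinition,
    ResidueKey,
    StructureModel,
)
from .trajectory import Trajectory

__all__ = [
    "SIX_DILUTIONS_NM",
    "DEFAULT_VANTHOFF_TEMPERATURES_K",
    "KineticReference",
    "REFERENCE_KINETICS",
    "TrajectorySpec",
    "TrajectoryGroundTruth",
    "make_toy_complex",
    "make_interface_standin",
    "INTERFACE_STANDIN_DISTANCES",
    "make_synthetic_trajectory",
    "make_sensorgram_panel",
    "make_kd_series",
    "make_thermogram",
    "make_nonbonded_params",
    "nonbonded_to_frame",
]

#: The standard six two-fold analyte dilutions (nM) used for SPR panels.
SIX_DILUTIONS_NM: tuple[float, ...] = (1000.0, 500.0, 250.0, 125.0, 62.5, 31.25)

#: Default temperature grid (K) for synthetic van't Hoff series.
DEFAULT_VANTHOFF_TEMPERATURES_K: tuple[float, ...] = (288.0, 292.4, 296.8, 301.2,
                                                      305.6, 310.0)


@dataclass(frozen=True)
class KineticReference:
    """Literature SPR rate constants for one antigen-antibody complex."""

    kon: float            # 1/(M*s)
    koff: float           # 1/s
    reported_kd_nm: float  # equilibrium KD as reported, nM

    @property
    def kd_nm(self) -> float:
        return 1e9 * self.koff / self.kon


#: SPR-derived kinetic parameters reported for the IFN-gamma-receptor / A6
#: antibody system: the wild-type pair, two antigen alanine mutants, and the
#: two charge-exchanged (swap-compensated) complexes that restore binding.
REFERENCE_KINETICS: dict[str, KineticReference] = {
    "Ag:WT-Ab:WT": KineticReference(kon=2.7e5, koff=2.3e-2, reported_kd_nm=87.0),
    "Ag:R84A-Ab:WT": KineticReference(kon=0.74e5, koff=2.1e-2, reported_kd_nm=280.0),
    "Ag:K98A-Ab:WT": KineticReference(kon=0.90e5, koff=3.9e-2, reported_kd_nm=440.0),
    "Ag:R84E-VL:E27R": KineticReference(kon=2.4e5, koff=1.7e-2, reported_kd_nm=73.0),
    "Ag:K98D-VL:D28K": KineticReference(kon=2.1e5, koff=2.0e-2, reported_kd_nm=95.0),
}


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise UsageError("zero-length direction vector")
    return v / n


def _perpendicular(v: np.ndarray) -> np.ndarray:
    v = _unit(v)
    trial = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = trial - v * (trial @ v)
    return _unit(p)


def _satellite(center: np.ndarray, target: np.ndarray, bond: float,
               distance: float, plane: np.ndarray | None = None) -> np.ndarray:
    """Place an atom at ``bond`` A from ``center`` and exactly ``distance`` A
    from ``target``, in the plane spanned by (target - center) and ``plane``."""
    center = np.asarray(center, float)
    target = np.asarray(target, float)
    axis = target - center
    length = float(np.linalg.norm(axis))
    cos_g = (length ** 2 + bond ** 2 - distance ** 2) / (2.0 * bond * length)
    if not -1.0 <= cos_g <= 1.0:
        raise GenerationError(
            f"cannot place satellite: bond {bond}, separation {length:.3f} and "
            f"target distance {distance} violate the triangle inequality"
        )
    e1 = axis / length
    e2 = _perpendicular(e1) if plane is None else _unit(plane - e1 * (plane @ e1))
    sin_g = math.sqrt(max(0.0, 1.0 - cos_g ** 2))
    return center + bond * (cos_g * e1 + sin_g * e2)


_GUANIDINE_BOND = 1.33   # CZ-N distances in the guanidinium group
_CARBOXYL_BOND = 1.25    # CG/CD-O distances in carboxylates


def _residue_atoms(res_name: str, rep_pos: np.ndarray, toward: np.ndarray,
                   away: np.ndarray) -> dict[str, np.ndarray]:
    """Idealized side-chain group + backbone for one charged residue.

    ``toward`` points at the interaction partner, ``away`` from it; both unit.
    Geometry is schematic (synthetic fixture), not force-field quality.
    """
    rep_pos = np.asarray(rep_pos, float)
    perp = _perpendicular(toward)
    atoms: dict[str, np.ndarray] = {}
    if res_name == "LYS":
        atoms["NZ"] = rep_pos
        atoms["CE"] = rep_pos + 1.5 * away
    elif res_name == "ARG":
        atoms["CZ"] = rep_pos
        atoms["NH1"] = rep_pos + _GUANIDINE_BOND * toward
        atoms["NE"] = rep_pos + _GUANIDINE_BOND * (-0.5 * toward + 0.866 * perp)
        atoms["NH2"] = rep_pos + _GUANIDINE_BOND * (-0.5 * toward - 0.866 * perp)
    elif res_name in {"ASP", "GLU"}:
        o1, o2 = ("OD1", "OD2") if res_name == "ASP" else ("OE1", "OE2")
        rep = "CG" if res_name == "ASP" else "CD"
        atoms[rep] = rep_pos
        atoms[o1] = rep_pos + _CARBOXYL_BOND * (0.866 * perp + 0.5 * away)
        atoms[o2] = rep_pos + _CARBOXYL_BOND * (-0.866 * perp + 0.5 * away)
    else:
        raise UsageError(f"{res_name!r} is not a charged residue type")
    ca = rep_pos + 4.0 * away
    atoms["CA"] = ca
    atoms["N"] = ca + np.array([0.0, 0.0, 1.2]) + 0.3 * away
    atoms["C"] = ca + np.array([0.0, 0.0, -1.2]) + 0.3 * away
    return atoms


def _filler_atoms(ca: np.ndarray) -> dict[str, np.ndarray]:
    ca = np.asarray(ca, float)
    return {
        "N": ca + np.array([-1.2, 0.6, 0.0]),
        "CA": ca,
        "C": ca + np.array([1.2, 0.6, 0.0]),
        "CB": ca + np.array([0.0, -1.0, 1.0]),
    }


def _add_residue(model: StructureModel, chain: str, seq: int, name: str,
                 atoms: dict[str, np.ndarray], serial_start: int) -> int:
    key = ResidueKey(chain_id=chain, res_seq=seq, i_code="", res_name=name)
    if key in model.residues:
        raise GenerationError(f"duplicate residue {key}")
    model.residues[key] = [
        AtomRecord(serial=serial_start + i, name=n, element=n[0], alt_loc="",
                   coords=np.asarray(c, float))
        for i, (n, c) in enumerate(atoms.items())
    ]
    return serial_start + len(atoms)


def _sort_model(model: StructureModel, chain_order: Sequence[str]) -> StructureModel:
    ordered = StructureModel(model.model_index)
    for chain in chain_order:
        for key in sorted(model.chain_residues(chain), key=lambda k: (k.res_seq, k.i_code)):
            ordered.residues[key] = model.residues[key]
    return ordered


# --------------------------------------------------------------------------
# toy complexes
# --------------------------------------------------------------------------

def make_toy_complex(n_res_a: int, n_res_b: int,
                     planted_pairs: Sequence[tuple[tuple[str, int, str],
                                                   tuple[str, int, str], float]],
                     seed: int = 0, chain_a: str = "A", chain_b: str = "B"
                     ) -> StructureModel:
    """Two-chain toy complex with charged pairs planted at exact distances.

    ``planted_pairs`` holds (basic residue, acidic residue, representative
    distance) triples, each residue given as (chain, res_seq, res_name) with
    chain in {chain_a, chain_b}.  Each pair is laid out in its own spatial
    slot 20 A from the next, so planted representative distances are exact to
    construction and all non-planted charged groups sit >= 8 A apart.
    Remaining residue counts are filled with alanine on well-separated grids.
    """
    basic_names = {"LYS", "ARG"}
    acidic_names = {"ASP", "GLU"}
    for basic, acidic, dist in planted_pairs:
        if dist <= 1.0:
            raise GenerationError(f"planted distance {dist} must exceed 1 A")
        if basic[2] not in basic_names:
            raise GenerationError(f"{basic[2]} is not a basic residue type")
        if acidic[2] not in acidic_names:
            raise GenerationError(f"{acidic[2]} is not an acidic residue type")
        for chain, _, _ in (basic, acidic):
            if chain not in {chain_a, chain_b}:
                raise GenerationError(f"unknown chain {chain!r} in planted pair")
    n_planted = {chain_a: 0, chain_b: 0}
    for basic, acidic, _ in planted_pairs:
        n_planted[basic[0]] += 1
        n_planted[acidic[0]] += 1
    if n_planted[chain_a] > n_res_a or n_planted[chain_b] > n_res_b:
        raise GenerationError("residue counts are smaller than the planted pairs")

    rng = np.random.default_rng(seed)
    model = StructureModel(model_index=1)
    serial = 1
    y_hat = np.array([0.0, 1.0, 0.0])

    for k, (basic, acidic, dist) in enumerate(planted_pairs):
        slot = np.array([20.0 * k, 0.0, 0.0])
        basic_rep = slot
        acidic_rep = slot + dist * y_hat
        serial = _add_residue(model, basic[0], basic[1], basic[2],
                              _residue_atoms(basic[2], basic_rep, y_hat, -y_hat),
                              serial)
        serial = _add_residue(model, acidic[0], acidic[1], acidic[2],
                              _residue_atoms(acidic[2], acidic_rep, -y_hat, y_hat),
                              serial)

    used_seq = {chain_a: {r[1] for p in planted_pairs for r in p[:2] if r[0] == chain_a},
                chain_b: {r[1] for p in planted_pairs for r in p[:2] if r[0] == chain_b}}
    for chain, n_total, row_y in ((chain_a, n_res_a, -30.0), (chain_b, n_res_b, 30.0)):
        n_fill = n_total - len(used_seq[chain])
        next_seq = max(used_seq[chain], default=0) + 1
        for j in range(n_fill):
            ca = np.array([20.0 * j, row_y, 0.0]) + rng.uniform(-2.0, 2.0, 3)
            serial = _add_residue(model, chain, next_seq + j, "ALA",
                                  _filler_atoms(ca), serial)
    return _sort_model(model, [chain_a, chain_b])


# --------------------------------------------------------------------------
# synthetic interface stand-in
# --------------------------------------------------------------------------

#: Planted side-chain distances (A) of the synthetic interface stand-in, keyed
#: by (contact, convention).  These are the published crystal-structure values
#: for the IFN-gamma-receptor / A6 interface; the stand-in reproduces them by
#: construction.
INTERFACE_STANDIN_DISTANCES: dict[tuple[str, str], float] = {
    ("K52-D54", "representative"): 3.6,   # Lys NZ - Asp CG
    ("K52-D54", "group_min"): 2.8,        # NZ to nearest carboxyl O
    ("K52-D56", "representative"): 3.5,
    ("R84-E45", "representative"): 4.3,   # Arg CZ - Glu CD (intra-antigen)
    ("R84-E45", "group_min"): 2.9,        # guanidinium N to carboxyl O
    ("R84-E27", "group_min"): 3.7,
    ("E27-K98", "representative"): 8.0,   # Glu CD - Lys NZ
    ("K98-D28", "group_min"): 4.3,
}


def make_interface_standin() -> StructureModel:
    """SYNTHETIC stand-in for the antigen-antibody interface of the
    IFN-gamma-receptor / A6 crystal structure.

    This is not the crystal structure: it is an idealized model holding only
    the eight key charged residues (antigen chain I: K52, E45, R84, K98; heavy
    chain H: D54, D56; light chain L: E27, D28) with their side-chain groups
    placed so that every distance in :data:`INTERFACE_STANDIN_DISTANCES`
    matches the published crystal value exactly.  It exists so the geometry
    conventions (representative-atom vs. group-minimum) can be exercised and
    demonstrated without downloading the real coordinates.
    """
    z_hat = np.array([0.0, 0.0, 1.0])
    y_hat = np.array([0.0, 1.0, 0.0])
    x_hat = np.array([1.0, 0.0, 0.0])

    model = StructureModel(model_index=1)
    serial = 1

    # --- K52 / D54 / D56 cluster --------------------------------------
    nz52 = np.array([0.0, 0.0, 0.0])
    atoms_k52 = {"NZ": nz52, "CE": nz52 + 1.5 * y_hat, "CA": nz52 + 4.5 * y_hat}
    atoms_k52["N"] = atoms_k52["CA"] + np.array([-1.2, 0.8, 0.0])
    atoms_k52["C"] = atoms_k52["CA"] + np.array([1.2, 0.8, 0.0])

    cg54 = nz52 + 3.6 * x_hat
    od1_54 = _satellite(cg54, nz52, _CARBOXYL_BOND, 2.8, plane=y_hat)
    atoms_d54 = {"CG": cg54, "OD1": od1_54, "OD2": cg54 + _CARBOXYL_BOND * x_hat,
                 "CA": cg54 + 4.0 * np.array([0.3, -0.954, 0.0])}
    atoms_d54["N"] = atoms_d54["CA"] + np.array([-1.2, -0.6, 0.0])
    atoms_d54["C"] = atoms_d54["CA"] + np.array([1.2, -0.6, 0.0])

    cg56 = nz52 - 3.5 * z_hat
    od1_56 = _satellite(cg56, nz52, _CARBOXYL_BOND, 2.8, plane=x_hat)
    atoms_d56 = {"CG": cg56, "OD1": od1_56, "OD2": cg56 - _CARBOXYL_BOND * z_hat,
                 "CA": cg56 + 4.0 * np.array([0.0, -1.0, 0.0])}
    atoms_d56["N"] = atoms_d56["CA"] + np.array([-1.2, -0.6, 0.0])
    atoms_d56["C"] = atoms_d56["CA"] + np.array([1.2, -0.6, 0.0])

    # --- R84 / E45 / E27 / K98 / D28 cluster --------------------------
    cz84 = np.array([30.0, 0.0, 0.0])
    nh1 = cz84 + _GUANIDINE_BOND * x_hat
    ne = cz84 + _GUANIDINE_BOND * np.array([-0.5, 0.866, 0.0])
    nh2 = cz84 + _GUANIDINE_BOND * np.array([-0.5, -0.866, 0.0])
    atoms_r84 = {"CZ": cz84, "NH1": nh1, "NE": ne, "NH2": nh2,
                 "CA": cz84 + 4.5 * z_hat}
    atoms_r84["N"] = atoms_r84["CA"] + np.array([-1.2, 0.0, 0.8])
    atoms_r84["C"] = atoms_r84["CA"] + np.array([1.2, 0.0, 0.8])

    cd45 = cz84 + 4.3 * x_hat
    oe1_45 = _satellite(cd45, nh1, _CARBOXYL_BOND, 2.9, plane=y_hat)
    atoms_e45 = {"CD": cd45, "OE1": oe1_45,
                 "OE2": cd45 + _CARBOXYL_BOND * np.array([0.5, -0.866, 0.0]),
                 "CA": cd45 - 4.5 * z_hat}
    atoms_e45["N"] = atoms_e45["CA"] + np.array([-1.2, 0.0, -0.8])
    atoms_e45["C"] = atoms_e45["CA"] + np.array([1.2, 0.0, -0.8])

    # E27: carboxyl O pointing at the guanidinium, group minimum 3.7 A to
    # NE/NH2, reached by solving along the -x axis from CZ84.
    target = ne
    # OE1 on the CZ-CD axis at CD + bond * x_hat; solve CD x-coordinate.
    #   |OE1 - NE|^2 = 3.7^2 with OE1 = (cd_x + 1.25, 0, 0)
    off = math.sqrt(3.7 ** 2 - ne[1] ** 2)
    cd27_x = ne[0] - off - _CARBOXYL_BOND
    cd27 = np.array([cd27_x, 0.0, 0.0])
    oe1_27 = cd27 + _CARBOXYL_BOND * x_hat
    atoms_e27 = {"CD": cd27, "OE1": oe1_27, "OE2": cd27 - _CARBOXYL_BOND * x_hat,
                 "CA": cd27 - 4.5 * y_hat}
    atoms_e27["N"] = atoms_e27["CA"] + np.array([-1.2, -0.6, 0.0])
    atoms_e27["C"] = atoms_e27["CA"] + np.array([1.2, -0.6, 0.0])

    nz98 = cd27 + 8.0 * y_hat
    atoms_k98 = {"NZ": nz98, "CE": nz98 + 1.5 * z_hat, "CA": nz98 + 4.5 * z_hat}
    atoms_k98["N"] = atoms_k98["CA"] + np.array([-1.2, 0.0, 0.8])
    atoms_k98["C"] = atoms_k98["CA"] + np.array([1.2, 0.0, 0.8])

    cg28 = nz98 + 5.0 * y_hat
    od1_28 = _satellite(cg28, nz98, _CARBOXYL_BOND, 4.3, plane=x_hat)
    atoms_d28 = {"CG": cg28, "OD1": od1_28, "OD2": cg28 + _CARBOXYL_BOND * y_hat,
                 "CA": cg28 + 4.5 * z_hat + 1.0 * y_hat}
    atoms_d28["N"] = atoms_d28["CA"] + np.array([-1.2, 0.6, 0.0])
    atoms_d28["C"] = atoms_d28["CA"] + np.array([1.2, 0.6, 0.0])

    for chain, seq, name, atoms in [
        ("I", 45, "GLU", atoms_e45),
        ("I", 52, "LYS", atoms_k52),
        ("I", 84, "ARG", atoms_r84),
        ("I", 98, "LYS", atoms_k98),
        ("H", 54, "ASP", atoms_d54),
        ("H", 56, "ASP", atoms_d56),
        ("L", 27, "GLU", atoms_e27),
        ("L", 28, "ASP", atoms_d28),
    ]:
        serial = _add_residue(model, chain, seq, name, atoms, serial)
    return _sort_model(model, ["I", "H", "L"])


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Recipe for a synthetic trajectory fluctuating around a reference model.

    Defaults mirror a standard production run: 10 000 frames at 10 ps spacing
    (100 ns) with 0.5 A isotropic positional jitter.  ``contact_targets`` maps
    contacts to target occupancies in [0, 1] (or to explicit boolean per-frame
    schedules); ``drift_a_per_ns`` > 0 makes ``drift_chain`` slide away at a
    constant velocity, emulating a dissociating complex.
    """

    reference: StructureModel
    jitter_sd: float = 0.5
    contact_targets: list[tuple[ContactDefinition, float | np.ndarray]] = \
        field(default_factory=list)
    drift_chain: str | None = None
    drift_a_per_ns: float = 0.0
    drift_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)
    n_frames: int = 10_000
    dt_ns: float = 0.01
    seed: int = 0

    #: in-contact and out-of-contact distances as multiples of the threshold
    in_factor: float = 0.8
    out_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise GenerationError("n_frames must be >= 1")
        if self.jitter_sd < 0 or self.drift_a_per_ns < 0:
            raise GenerationError("jitter and drift must be non-negative")
        for _, target in self.contact_targets:
            if np.isscalar(target) and not 0.0 <= float(target) <= 1.0:
                raise GenerationError("target occupancies must lie in [0, 1]")


@dataclass
class TrajectoryGroundTruth:
    """What the generator actually did: per-contact schedules and realized
    occupancies, the drift velocity vector (A/ns), jitter and seed."""

    schedules: dict[str, np.ndarray]
    target_occupancy: dict[str, float]
    realized_occupancy: dict[str, float]
    drift_chain: str | None
    drift_vector: np.ndarray
    jitter_sd: float
    seed: int


def make_synthetic_trajectory(spec: TrajectorySpec
                              ) -> tuple[Trajectory, TrajectoryGroundTruth]:
    """Generate a trajectory per ``spec`` along with its ground truth.

    Frames are the reference plus iid Gaussian jitter.  Atoms of residues
    involved in contact targets are exempt from jitter and placed
    deterministically: in Bernoulli-scheduled "in" frames the pair's
    representative distance equals ``in_factor * threshold`` and otherwise
    ``out_factor * threshold``, so the measured occupancy of the realized
    schedule is exact.  Drift adds t * v to every atom of the drifting chain.
    """
    rng = np.random.default_rng(spec.seed)
    topo = spec.reference
    ref_coords = topo.coords()
    n_atoms = ref_coords.shape[0]
    index = topo.flat_index()
    times = np.arange(spec.n_frames) * spec.dt_ns

    # residue -> flat atom indices
    res_atoms: dict[tuple[str, int, str], list[int]] = {}
    for (chain, seq, icode, _name), i in index.items():
        res_atoms.setdefault((chain, seq, icode), []).append(i)

    frames = ref_coords[None, :, :] + rng.normal(
        0.0, spec.jitter_sd, size=(spec.n_frames, n_atoms, 3))

    claimed: set[tuple[str, int, str]] = set()
    schedules: dict[str, np.ndarray] = {}
    targets: dict[str, float] = {}
    realized: dict[str, float] = {}

    for contact, target in spec.contact_targets:
        ka = topo.resolve(contact.res_a)
        kb = topo.resolve(contact.res_b)
        for key in ((ka.chain_id, ka.res_seq, ka.i_code),
                    (kb.chain_id, kb.res_seq, kb.i_code)):
            if key in claimed:
                raise GenerationError(
                    f"contact {contact.label!r} shares residue {key} with another "
                    "target: schedules would contradict each other"
                )
            claimed.add(key)
        if spec.drift_chain in (ka.chain_id, kb.chain_id) and spec.drift_a_per_ns > 0:
            raise GenerationError(
                f"contact {contact.label!r} involves the drifting chain "
                f"{spec.drift_chain!r}"
            )

        ia = index[(ka.chain_id, ka.res_seq, ka.i_code, contact.atom_a)]
        ib = index[(kb.chain_id, kb.res_seq, kb.i_code, contact.atom_b)]
        axis = ref_coords[ib] - ref_coords[ia]
        d_ref = float(np.linalg.norm(axis))
        u = axis / d_ref

        if np.isscalar(target):
            sched = rng.random(spec.n_frames) < float(target)
            targets[contact.label] = float(target)
        else:
            sched = np.asarray(target, dtype=bool)
            if sched.shape != (spec.n_frames,):
                raise GenerationError(
                    f"explicit schedule for {contact.label!r} must have "
                    f"{spec.n_frames} entries"
                )
            targets[contact.label] = float(sched.mean())
        d_t = np.where(sched, spec.in_factor * contact.threshold,
                       spec.out_factor * contact.threshold)

        idx_a = res_atoms[(ka.chain_id, ka.res_seq, ka.i_code)]
        idx_b = res_atoms[(kb.chain_id, kb.res_seq, kb.i_code)]
        frames[:, idx_a, :] = ref_coords[idx_a]       # jitter-free anchor
        frames[:, idx_b, :] = ref_coords[idx_b]
        frames[:, idx_b, :] += ((d_t - d_ref)[:, None, None] * u[None, None, :])

        schedules[contact.label] = sched
        realized[contact.label] = float(sched.mean())

    drift_vector = np.zeros(3)
    if spec.drift_chain is not None and spec.drift_a_per_ns > 0:
        drift_vector = spec.drift_a_per_ns * _unit(np.asarray(spec.drift_direction))
        chain_idx = [i for (c, _s, _i, _n), i in index.items() if c == spec.drift_chain]
        if not chain_idx:
            raise GenerationError(f"drift chain {spec.drift_chain!r} not in reference")
        frames[:, chain_idx, :] += times[:, None, None] * drift_vector[None, None, :]

    traj = Trajectory(topology=topo, frames=frames, times=times)
    truth = TrajectoryGroundTruth(
        schedules=schedules, target_occupancy=targets, realized_occupancy=realized,
        drift_chain=spec.drift_chain, drift_vector=drift_vector,
        jitter_sd=spec.jitter_sd, seed=spec.seed,
    )
    return traj, truth


# --------------------------------------------------------------------------
# SPR / thermodynamics / DSC
# --------------------------------------------------------------------------

def make_sensorgram_panel(kon: float, koff: float, rmax: float = 100.0,
                          concentrations_nm: Sequence[float] = SIX_DILUTIONS_NM,
                          schedule: PhaseSchedule = PhaseSchedule(),
                          noise_sd: float = 0.0,
                          seed: int | None = None) -> list[Sensorgram]:
    """Panel of 1:1 Langmuir sensorgrams at the given analyte dilutions (nM)."""
    rng = np.random.default_rng(seed)
    return [
        simulate_sensorgram(kon, koff, rmax, conc_nm * 1e-9, schedule=schedule,
                            noise_sd=noise_sd, rng=rng)
        for conc_nm in concentrations_nm
    ]


def make_kd_series(dh: float, ds: float,
                   temperatures: Sequence[float] = DEFAULT_VANTHOFF_TEMPERATURES_K,
                   noise_frac: float = 0.0,
                   seed: int | None = None) -> list[tuple[float, float]]:
    """KD(T) series from van't Hoff parameters: ln KD = dH/RT - dS/R.

    ``dh`` in kJ/mol, ``ds`` in kJ/(mol*K), temperatures in K.  Multiplicative
    log-normal noise of fractional scale ``noise_frac`` is applied to KD.
    """
    rng = np.random.default_rng(seed)
    out = []
    for t in temperatures:
        ln_kd = dh / (R_GAS_KJ * t) - ds / R_GAS_KJ
        kd = math.exp(ln_kd)
        if noise_frac > 0:
            kd *= math.exp(rng.normal(0.0, noise_frac))
        out.append((float(t), kd))
    return out


def make_thermogram(tm_c: float = 70.0, width_c: float = 4.0,
                    t_min_c: float = 40.0, t_max_c: float = 90.0,
                    step_c: float = 0.1, amplitude: float = 1.0,
                    baseline: float = 0.0,
                    extra_peaks: Sequence[tuple[float, float, float]] = (),
                    noise_sd: float = 0.0,
                    seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-peak DSC thermogram; ``extra_peaks`` adds (tm, width, amplitude)
    shoulders for multi-peak scenarios.  Returns (T in deg C, Cp)."""
    rng = np.random.default_rng(seed)
    t = np.arange(t_min_c, t_max_c + 0.5 * step_c, step_c)
    cp = baseline + amplitude * np.exp(-0.5 * ((t - tm_c) / width_c) ** 2)
    for tm2, w2, a2 in extra_peaks:
        cp = cp + a2 * np.exp(-0.5 * ((t - tm2) / w2) ** 2)
    if noise_sd > 0:
        cp = cp + rng.normal(0.0, noise_sd, size=t.shape)
    return t, cp


# --------------------------------------------------------------------------
# nonbonded parameters for toy systems
# --------------------------------------------------------------------------

def make_nonbonded_params(model: StructureModel, default_sigma: float = 3.2,
                          default_epsilon: float = 0.4) -> NonbondedParams:
    """Uniform-LJ parameter table with unit formal charges on charged groups.

    Basic side-chain groups carry +1 e (split equally over their group atoms)
    and acidic groups -1 e; every other atom is neutral.  One sigma/epsilon is
    used throughout — adequate for exercising the decomposition, not a force
    field.
    """
    table: dict[tuple[str, int, str, str], tuple[float, float, float]] = {}
    for key, atom_list in model.residues.items():
        group = DEFAULT_CHARGED_GROUPS.get(key.res_name)
        group_atoms = set(group.group_atoms) if group else set()
        present = [a.name for a in atom_list if a.name in group_atoms]
        per_atom = 0.0
        if group and present:
            total = 1.0 if group.polarity == "basic" else -1.0
            per_atom = total / len(present)
        for atom in atom_list:
            q = per_atom if atom.name in group_atoms else 0.0
            table[(key.chain_id, key.res_seq, key.i_code, atom.name)] = (
                q, default_sigma, default_epsilon)
    return NonbondedParams(table=table)


def nonbonded_to_frame(model: StructureModel, params: NonbondedParams):
    """Parameter table as a DataFrame with the on-disk column layout."""
    import pandas as pd

    rows = []
    for key, atom_list in model.residues.items():
        for atom in atom_list:
            q, sigma, eps = params.table[(key.chain_id, key.res_seq, key.i_code,
                                          atom.name)]
            rows.append(dict(chain=key.chain_id, res_seq=key.res_seq,
                             i_code=key.i_code, res_name=key.res_name,
                             atom=atom.name, charge_e=q, sigma_A=sigma,
                             epsilon_kJmol=eps))
    return pd.DataFrame(rows)
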