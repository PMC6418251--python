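"""Per-residue nonbonded interaction-energy decomposition.

Decomposes the interaction of a chosen residue with partner chains into
Coulomb and 12-6 Lennard-Jones terms, averaged over the post-burn-in frames
of a trajectory and aggregated across replicas with a standard error.  This
is the short-range pairwise part of a force-field interaction energy: plain
truncation at the cutoff, no switching function and no reciprocal-space
(PME) term, which cannot be assigned to individual residue pairs.  The
decomposition therefore differs systematically from full-electrostatics
rerun energies; it is the per-residue hot-spot ranking that is meaningful.

Parameters (partial charges, LJ sigma/epsilon per atom) are supplied by
file — nothing is hard-coded from any force field.  Units are kJ/mol and
Angstrom (charges in elementary charge units); combining rules are
Lorentz-Berthelot unless explicit pair parameters are given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MissingParameterError, UsageError
from .structures import ResidueKey, StructureModel
from .trajectory import Trajectory, replica_summary

__all__ = [
    "COULOMB_CONSTANT",
    "KCAL_PER_KJ",
    "NonbondedParams",
    "EnergyBreakdown",
    "coulomb_energy",
    "lj_energy",
    "residue_interaction_energy",
    "aggregate_replicas",
    "energies_to_frame",
]

#: Coulomb prefactor f = 1/(4 pi eps0) in kJ * A / (mol * e^2).
COULOMB_CONSTANT = 1389.35458

KCAL_PER_KJ = 1.0 / 4.184

#: Default short-range cutoff in A for both Coulomb and LJ terms.
DEFAULT_CUTOFF_A = 12.0


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class NonbondedParams:
    """Per-atom nonbonded parameters keyed by (chain, res_seq, i_code, atom name).

    ``table`` maps each atom key to (charge_e, sigma_A, epsilon_kJmol).
    Optional ``pair_overrides`` maps frozensets of two atom keys to explicit
    (sigma_ij, epsilon_ij), taking precedence over Lorentz-Berthelot combining.
    """

    table: dict[tuple[str, int, str, str], tuple[float, float, float]]
    pair_overrides: dict[frozenset, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for key, (q, sigma, eps) in self.table.items():
            if sigma <= 0:
                raise UsageError(f"sigma must be positive for atom {key}")
            if eps < 0:
                raise UsageError(f"epsilon must be non-negative for atom {key}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NonbondedParams":
        """Build from a table with columns chain, res_seq, res_name, atom,
        charge_e, sigma_A, epsilon_kJmol (``i_code`` optional)."""
        required = {"chain", "res_seq", "atom", "charge_e", "sigma_A", "epsilon_kJmol"}
        missing = required - set(frame.columns)
        if missing:
            raise UsageError(f"parameter table lacks columns: {sorted(missing)}")
        table = {}
        for row in frame.itertuples(index=False):
            raw_icode = getattr(row, "i_code", "")
            if raw_icode is None or (isinstance(raw_icode, float)
                                     and math.isnan(raw_icode)):
                raw_icode = ""
            icode = str(raw_icode).strip()
            key = (str(row.chain), int(row.res_seq), icode, str(row.atom))
            table[key] = (float(row.charge_e), float(row.sigma_A),
                          float(row.epsilon_kJmol))
        return cls(table=table)

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "NonbondedParams":
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def lookup(self, atom_keys: Iterable[tuple[str, int, str, str]]
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised (charges, sigmas, epsilons) for the given atom keys.

        Refuses to run if any atom is unparameterised, listing the culprits.
        """
        keys = list(atom_keys)
        missing = [k for k in keys if k not in self.table]
        if missing:
            pretty = ", ".join(f"{c}:{s}{i}:{a}" for c, s, i, a in missing[:10])
            more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
            raise MissingParameterError(
                f"{len(missing)} atom(s) lack nonbonded parameters: {pretty}{more}"
            )
        arr = np.array([self.table[k] for k in keys], dtype=float)
        return arr[:, 0], arr[:, 1], arr[:, 2]


@dataclass
class EnergyBreakdown:
    """Coulomb + LJ interaction energy of one residue with its partner chains.

    Energies in kJ/mol; ``se`` is the standard error of the total across
    replicas (NaN with a single replica).
    """

    residue: ResidueKey
    coulomb: float
    lj: float
    total: float
    se: float
    n_replicas: int

    def __post_init__(self) -> None:
        if abs(self.total - (self.coulomb + self.lj)) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("total must equal coulomb + lj")


# --------------------------------------------------------------------------
# pair potentials
# --------------------------------------------------------------------------

def coulomb_energy(q1: float, q2: float, r: float, dielectric: float = 1.0) -> float:
    """Coulomb pair energy f * q1 * q2 / (dielectric * r) in kJ/mol (r in A, q in e)."""
    if r <= 0:
        raise UsageError("Coulomb energy is singular at r <= 0")
    return COULOMB_CONSTANT * q1 * q2 / (dielectric * r)


def lj_energy(sigma_ij: float, epsilon_ij: float, r: float) -> float:
    """12-6 Lennard-Jones pair energy 4*eps*[(sigma/r)^12 - (sigma/r)^6] in kJ/mol."""
    if r <= 0:
        raise UsageError("Lennard-Jones energy is singular at r <= 0")
    sr6 = (sigma_ij / r) ** 6
    return 4.0 * epsilon_ij * (sr6 * sr6 - sr6)


# --------------------------------------------------------------------------
# per-residue decomposition
# --------------------------------------------------------------------------

def _atom_keys_of(model: StructureModel, keys: Sequence[ResidueKey]
                  ) -> tuple[list[tuple[str, int, str, str]], list[int]]:
    index = model.flat_index()
    atom_keys, flat = [], []
    for key in keys:
        for atom in model.residues[key]:
            k = (key.chain_id, key.res_seq, key.i_code, atom.name)
            atom_keys.append(k)
            flat.append(index[k])
    return atom_keys, flat


def residue_interaction_energy(traj: Trajectory, params: NonbondedParams,
                               residue: ResidueKey, partner_chains: Iterable[str],
                               cutoff: float = DEFAULT_CUTOFF_A,
                               burn_in: float = 0.0,
                               dielectric: float = 1.0) -> EnergyBreakdown:
    """Time-averaged Coulomb + LJ energy of ``residue`` against partner chains.

    For every post-burn-in frame, all (residue atom, partner atom) pairs within
    ``cutoff`` A contribute; the per-frame sums are averaged over the window.
    Only inter-chain pairs are summed, so intramolecular 1-2/1-3/1-4 exclusions
    never arise.  Returns a single-replica breakdown (se = NaN, n = 1); use
    :func:`aggregate_replicas` to combine repeats.
    """
    topo = traj.topology
    res_key = topo.resolve(residue)
    partner_chains = set(partner_chains)
    if not partner_chains:
        raise UsageError("partner chain selection is empty")
    if res_key.chain_id in partner_chains:
        raise UsageError(
            f"partner chains must exclude the residue's own chain {res_key.chain_id!r}"
        )
    partner_res = [k for k in topo.residues if k.chain_id in partner_chains]
    if not partner_res:
        raise UsageError(f"no residues found in partner chains {sorted(partner_chains)}")

    res_atom_keys, res_idx = _atom_keys_of(topo, [res_key])
    par_atom_keys, par_idx = _atom_keys_of(topo, partner_res)
    q_a, sig_a, eps_a = params.lookup(res_atom_keys)
    q_b, sig_b, eps_b = params.lookup(par_atom_keys)

    # pair matrices, computed once
    qq = COULOMB_CONSTANT * np.outer(q_a, q_b) / dielectric
    sig_ij = 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps_ij = np.sqrt(np.outer(eps_a, eps_b))
    if params.pair_overrides:
        for i, ka in enumerate(res_atom_keys):
            for j, kb in enumerate(par_atom_keys):
                override = params.pair_overrides.get(frozenset((ka, kb)))
                if override is not None:
                    sig_ij[i, j], eps_ij[i, j] = override

    keep = traj.times >= burn_in
    if not keep.any():
        raise UsageError(f"no frames at or after burn-in of {burn_in} ns")
    res_idx_arr = np.asarray(res_idx)
    par_idx_arr = np.asarray(par_idx)

    coul_frames, lj_frames = [], []
    for frame in traj.frames[keep]:
        diff = frame[res_idx_arr][:, None, :] - frame[par_idx_arr][None, :, :]
        r = np.sqrt((diff ** 2).sum(axis=-1))
        within = (r <= cutoff) & (r > 0)
        inv_r = np.where(within, 1.0 / np.where(r > 0, r, 1.0), 0.0)
        coul = float(np.sum(qq * inv_r * within))
        sr6 = np.where(within, (sig_ij * inv_r) ** 6, 0.0)
        lj = float(np.sum(4.0 * eps_ij * (sr6 * sr6 - sr6)))
        coul_frames.append(coul)
        lj_frames.append(lj)

    coulomb = float(np.mean(coul_frames))
    lj = float(np.mean(lj_frames))
    return EnergyBreakdown(residue=res_key, coulomb=coulomb, lj=lj,
                           total=coulomb + lj, se=math.nan, n_replicas=1)


def aggregate_replicas(breakdowns: Sequence[EnergyBreakdown]) -> EnergyBreakdown:
    """Mean across replica breakdowns with the standard error of the total.

    Energy tables report standard errors (se = sd/sqrt(n)) across independent
    repeat trajectories, as opposed to the sd convention used for occupancies.
    """
    if not breakdowns:
        raise UsageError("need at least one replica breakdown")
    residues = {(b.residue.chain_id, b.residue.res_seq, b.residue.i_code)
                for b in breakdowns}
    if len(residues) > 1:
        raise UsageError("replica breakdowns refer to different residues")
    coulomb = float(np.mean([b.coulomb for b in breakdowns]))
    lj = float(np.mean([b.lj for b in breakdowns]))
    stats = replica_summary([b.total for b in breakdowns])
    return EnergyBreakdown(residue=breakdowns[0].residue, coulomb=coulomb, lj=lj,
                           total=coulomb + lj, se=stats.se,
                           n_replicas=len(breakdowns))


def energies_to_frame(breakdowns: Sequence[EnergyBreakdown],
                      kcal: bool = False) -> pd.DataFrame:
    """Tabulate aggregated breakdowns (one row per residue), optionally in kcal/mol."""
    f = KCAL_PER_KJ if kcal else 1.0
    unit = "kcal/mol" if kcal else "kJ/mol"
    rows = [dict(residue=str(b.residue), coulomb=b.coulomb * f, lj=b.lj * f,
                 total=b.total * f, se=b.se * f, n=b.n_replicas, unit=unit)
            for b in breakdowns]
    return pd.DataFrame(rows, columns=["residue", "coulomb", "lj", "total", "se",
                                       "n", "unit"])
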