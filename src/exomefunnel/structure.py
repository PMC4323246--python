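"""Trimer-model plausibility screening and RMSD convergence analysis.

A homo-trimer of Ig-like extracellular domains is the minimal complex that
could hold a membrane protein at a tricellular contact, with each chain's
C-terminus pointing toward its own cell membrane.  Candidate docked trimer
models are screened by three criteria:

1. *membrane plausibility* — the C-terminus of each chain must not be buried
   inside the complex (operationalized as a foreign-heavy-atom neighbor count
   around the C-terminal Calpha);
2. *interface energy* — an externally computed docking score, consumed as
   input metadata and never recomputed here;
3. *polar interface contacts* — the number of cross-chain N/O heavy-atom
   pairs within hydrogen-bonding distance.

For dynamics output, a per-residue RMSD series over trajectory frames (after
least-squares superposition on a reference selection) is reduced to a
converged/not-converged verdict from the spread of its final window: a locally
stable site settles to a narrow band, an unstable one keeps wandering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Chain",
    "TrimerModel",
    "RmsdSeries",
    "ConvergenceResult",
    "ScreenEntry",
    "kabsch",
    "superpose",
    "c_terminus_exposed",
    "count_polar_interface_contacts",
    "rank_models",
    "residue_rmsd_series",
    "assess_convergence",
    "read_trimer_pdb",
    "write_trimer_pdb",
    "read_trajectory_pdb",
]

_KNOWN_ELEMENTS = {"H", "C", "N", "O", "S", "P", "SE", "F", "CL", "BR", "I"}
_POLAR_ELEMENTS = {"N", "O"}


@dataclass
class Chain:
    """One chain of a model: parallel per-atom arrays plus the residue index
    of the chain's C-terminal residue."""

    chain_id: str
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    c_term_index: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        for arr in (self.res_ids, self.res_names, self.atom_names, self.elements):
            if len(arr) != n:
                raise ValueError("per-atom arrays must have equal length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.c_term_index not in set(int(r) for r in self.res_ids):
            raise ValueError(f"c_term_index {self.c_term_index} not a residue of chain")

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])


@dataclass
class TrimerModel:
    """A candidate symmetric trimer: exactly three chains, optionally carrying
    an externally computed interface energy (lower is better)."""

    chains: tuple
    external_score: Optional[float] = None
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.chains) != 3:
            raise ValueError("a trimer model must have exactly 3 chains")


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Angstrom) of a residue selection after superposition."""

    frame_times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.frame_times) != len(self.values):
            raise ValueError("frame_times and values must have equal length")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be >= 0")


@dataclass(frozen=True)
class ConvergenceResult:
    converged: bool
    mean: float
    spread: float


@dataclass(frozen=True)
class ScreenEntry:
    model: TrimerModel
    score: float
    exposed: bool
    polar_contacts: int


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid transform (R, t) minimizing ||R @ mobile + t - target||.

    Standard SVD solution with the determinant sign fix, so the result is a
    proper rotation (no reflection).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("point sets must have identical shape")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    rot, t = kabsch(mobile, target)
    return mobile @ rot.T + t


# ---------------------------------------------------------------------------
# Trimer screening
# ---------------------------------------------------------------------------


def c_terminus_exposed(
    m: TrimerModel, radius: float = 10.0, max_neighbors: int = 10
) -> tuple:
    """Per-chain exposure verdicts for the C-terminal Calpha.

    A chain's C-terminus is *buried* iff more than ``max_neighbors`` heavy
    atoms from the other two chains lie within ``radius`` Angstrom of its
    C-terminal Calpha.  Raises if a chain lacks a Calpha at its C-terminal
    residue.
    """
    verdicts = []
    for i, chain in enumerate(m.chains):
        sel = (chain.res_ids == chain.c_term_index) & (chain.atom_names == "CA")
        if not np.any(sel):
            raise ValueError(
                f"chain {chain.chain_id!r}: no CA atom at C-terminal residue "
                f"{chain.c_term_index}"
            )
        ca = chain.coords[np.nonzero(sel)[0][0]]
        count = 0
        for j, other in enumerate(m.chains):
            if j == i:
                continue
            foreign = other.coords[other.heavy_mask]
            if len(foreign):
                count += int(np.sum(np.linalg.norm(foreign - ca, axis=1) <= radius))
        verdicts.append(count <= max_neighbors)
    return tuple(verdicts)


def _polar_atoms(chain: Chain) -> np.ndarray:
    keep = []
    for k, e in enumerate(chain.elements):
        eu = str(e).upper()
        if eu not in _KNOWN_ELEMENTS:
            warnings.warn(
                f"chain {chain.chain_id!r}: unknown element {e!r} for atom "
                f"{chain.atom_names[k]!r}; atom skipped"
            )
            continue
        if eu in _POLAR_ELEMENTS:
            keep.append(k)
    return chain.coords[keep] if keep else np.empty((0, 3))


def count_polar_interface_contacts(m: TrimerModel, cutoff: float = 3.5) -> int:
    """Count unordered cross-chain pairs of N/O heavy atoms within ``cutoff``.

    N and O atoms are the donor/acceptor-capable heavy atoms; no angular
    hydrogen-bond criterion is applied.  Symmetric in chain order.
    """
    polar = [_polar_atoms(c) for c in m.chains]
    total = 0
    for i in range(3):
        for j in range(i + 1, 3):
            if len(polar[i]) == 0 or len(polar[j]) == 0:
                continue
            tree = cKDTree(polar[j])
            total += int(sum(len(hits) for hits in tree.query_ball_point(polar[i], cutoff)))
    return total


def rank_models(
    models: Sequence[TrimerModel],
    top_fraction: float = 0.01,
    radius: float = 10.0,
    max_neighbors: int = 10,
    contact_cutoff: float = 3.5,
) -> list:
    """Shortlist docked trimer models by the three selection criteria.

    Takes the best ``ceil(top_fraction * N)`` models by external interface
    energy (lower is better), drops models with any buried C-terminus, and
    orders the remainder by (energy ascending, polar contacts descending),
    with input order as the deterministic tie-break.  Returns
    :class:`ScreenEntry` records.  Raises if any model lacks a score.
    """
    models = list(models)
    for m in models:
        if m.external_score is None:
            raise ValueError(f"model {m.name!r} has no external interface score")
    if not models:
        return []
    k = math.ceil(top_fraction * len(models))
    order = sorted(range(len(models)), key=lambda i: (models[i].external_score, i))
    top = order[:k]
    entries = []
    for i in top:
        m = models[i]
        exposed = all(c_terminus_exposed(m, radius=radius, max_neighbors=max_neighbors))
        if not exposed:
            continue
        contacts = count_polar_interface_contacts(m, cutoff=contact_cutoff)
        entries.append((i, ScreenEntry(m, float(m.external_score), True, contacts)))
    if not entries:
        warnings.warn("all shortlisted models have a buried C-terminus; empty shortlist")
        return []
    entries.sort(key=lambda pair: (pair[1].score, -pair[1].polar_contacts, pair[0]))
    return [e for _, e in entries]


# ---------------------------------------------------------------------------
# RMSD over trajectories
# ---------------------------------------------------------------------------


def residue_rmsd_series(
    traj_coords: np.ndarray,
    ref_coords: np.ndarray,
    target_idx: np.ndarray,
    superpose_idx: np.ndarray,
    frame_times: Optional[np.ndarray] = None,
) -> RmsdSeries:
    """Per-frame RMSD of target atoms after superposition on reference atoms.

    ``traj_coords`` has shape (n_frames, n_atoms, 3) with positional atom
    correspondence to ``ref_coords`` (n_atoms, 3).  Each frame is rigidly
    superposed onto the reference using the ``superpose_idx`` atoms, then the
    RMSD over ``target_idx`` atoms is recorded.
    """
    traj_coords = np.asarray(traj_coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    if traj_coords.ndim != 3 or traj_coords.shape[2] != 3:
        raise ValueError("traj_coords must have shape (n_frames, n_atoms, 3)")
    if traj_coords.shape[1] != ref_coords.shape[0]:
        raise ValueError(
            f"atom count mismatch: trajectory has {traj_coords.shape[1]}, "
            f"reference has {ref_coords.shape[0]}"
        )
    target_idx = np.asarray(target_idx)
    superpose_idx = np.asarray(superpose_idx)
    ref_sup = ref_coords[superpose_idx]
    ref_tgt = ref_coords[target_idx]
    values = np.empty(len(traj_coords))
    for f, frame in enumerate(traj_coords):
        rot, t = kabsch(frame[superpose_idx], ref_sup)
        moved = frame[target_idx] @ rot.T + t
        values[f] = math.sqrt(float(np.mean(np.sum((moved - ref_tgt) ** 2, axis=1))))
    if frame_times is None:
        frame_times = np.arange(len(values), dtype=float)
    return RmsdSeries(frame_times=frame_times, values=values)


def assess_convergence(
    s: RmsdSeries, window_fraction: float = 0.5, spread_tol: float = 1.0
) -> ConvergenceResult:
    """Convergence verdict from the spread of the trailing window.

    The final ``window_fraction`` of frames (at least 10) is examined;
    the series is converged iff max - min over that window is at most
    ``spread_tol`` Angstrom.  The verdict is monotone in ``spread_tol``.
    """
    n = len(s.values)
    w = math.ceil(window_fraction * n)
    if w < 10:
        raise ValueError(f"too few frames in window ({w}); need >= 10")
    window = s.values[-w:]
    spread = float(window.max() - window.min())
    return ConvergenceResult(
        converged=spread <= spread_tol,
        mean=float(window.mean()),
        spread=spread,
    )


# ---------------------------------------------------------------------------
# PDB input/output (biotite-backed)
# ---------------------------------------------------------------------------


def _chains_from_atom_array(arr) -> list:
    chains = []
    for cid in sorted(set(arr.chain_id)):
        sub = arr[arr.chain_id == cid]
        res_ids = np.asarray(sub.res_id, dtype=int)
        atom_names = np.asarray(sub.atom_name, dtype=str)
        # C-terminus: highest residue that has a Calpha (skips appended
        # non-polymer groups); fall back to the highest residue id
        with_ca = res_ids[atom_names == "CA"]
        c_term = int(with_ca.max()) if len(with_ca) else int(res_ids.max())
        chains.append(
            Chain(
                chain_id=str(cid),
                res_ids=res_ids,
                res_names=np.asarray(sub.res_name, dtype=str),
                atom_names=atom_names,
                elements=np.asarray(sub.element, dtype=str),
                coords=np.asarray(sub.coord, dtype=float),
                c_term_index=c_term,
            )
        )
    return chains


def read_trimer_pdb(path, external_score: Optional[float] = None, name: str = "") -> TrimerModel:
    """Read a single-model, three-chain PDB file into a :class:`TrimerModel`.

    The C-terminal residue of each chain defaults to its highest residue id.
    The interface energy, if available, is supplied by the caller (it usually
    lives in a companion score table, not in the coordinate file).
    """
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    chains = _chains_from_atom_array(arr)
    if len(chains) != 3:
        raise ValueError(f"{path}: expected 3 chains, found {len(chains)}")
    return TrimerModel(chains=tuple(chains), external_score=external_score, name=name or str(path))


def write_trimer_pdb(m: TrimerModel, path) -> None:
    """Write a trimer model as a PDB file (one MODEL, three chains)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = sum(len(c.coords) for c in m.chains)
    arr = struc.AtomArray(n)
    i = 0
    for c in m.chains:
        k = len(c.coords)
        arr.chain_id[i : i + k] = c.chain_id
        arr.res_id[i : i + k] = c.res_ids
        arr.res_name[i : i + k] = c.res_names
        arr.atom_name[i : i + k] = c.atom_names
        arr.element[i : i + k] = c.elements
        arr.coord[i : i + k] = c.coords
        i += k
    arr.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_trajectory_pdb(path):
    """Read a multi-MODEL PDB trajectory.

    Returns ``(coords, template)`` where ``coords`` has shape
    (n_frames, n_atoms, 3) and ``template`` is a biotite AtomArray describing
    the atoms (positional correspondence across frames).
    """
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure()
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
        template = stack
    else:
        template = stack[0]
    return coords, template
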