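"""Trajectory stability analytics for ligand–protein MD runs.

Superposition RMSD time series, radius of gyration, per-atom/per-residue
RMSF, geometric hydrogen-bond statistics with occupancy filtering, Cartesian
PCA with global-motion removal, and a Boltzmann-inverted free-energy
landscape over the leading principal components.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AtomSelection, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondStat",
    "PCAResult",
    "FreeEnergySurface",
    "select_atoms",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rmsf",
    "hbond_stats",
    "trajectory_pca",
    "free_energy_landscape",
    "binding_site_selection",
]

logger = logging.getLogger(__name__)

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL = 0.0019872041


# ---------------------------------------------------------------------------
# atom selection mini-grammar
# ---------------------------------------------------------------------------

def select_atoms(traj: Trajectory, definition: str) -> AtomSelection:
    """Resolve a selection string against the trajectory's atom table.

    Grammar: ``and``-joined terms from {``protein``, ``ligand``, ``solvent``,
    ``backbone``, ``heavy``, ``resid A-B`` (inclusive), ``name X``}.
    Example: ``"protein and backbone"``.
    """
    atoms = traj.atoms
    mask = np.ones(len(atoms), dtype=bool)
    for term in [t.strip() for t in definition.split(" and ")]:
        if term in ("protein", "ligand", "solvent"):
            mask &= (atoms["chain"] == term).to_numpy()
        elif term == "backbone":
            mask &= atoms["backbone"].to_numpy()
        elif term == "heavy":
            mask &= (atoms["element"] != "H").to_numpy()
        elif m := re.fullmatch(r"resid\s+(\d+)(?:-(\d+))?", term):
            lo = int(m.group(1))
            hi = int(m.group(2) or lo)
            resids = atoms["residue_index"].to_numpy()
            mask &= (resids >= lo) & (resids <= hi)
        elif m := re.fullmatch(r"name\s+(\S+)", term):
            mask &= (atoms["atom_name"] == m.group(1)).to_numpy()
        else:
            raise ValueError(f"cannot parse selection term {term!r}")
    return AtomSelection(indices=np.flatnonzero(mask), definition=definition)


def _resolve(traj: Trajectory, sel) -> np.ndarray:
    if sel is None:
        return np.arange(traj.n_atoms)
    if isinstance(sel, str):
        return select_atoms(traj, sel).indices
    if isinstance(sel, AtomSelection):
        return sel.indices
    return np.asarray(sel, dtype=int)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray, fit_indices: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, SVD form).

    Finds the proper rotation ``R`` and translation ``t`` minimising
    ``|R·mobile + t − reference|²`` over the fit atoms (reflections are
    excluded via the determinant correction).  Returns ``(R, t, rmsd)`` with
    the RMSD evaluated over the fit atoms after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(mobile.shape[0]) if fit_indices is None else np.asarray(fit_indices, dtype=int)
    if idx.size < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    a = mobile[idx]
    b = reference[idx]
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    # rank-deficient cross-covariance => collinear/degenerate fit set
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    D = np.diag([1.0, 1.0, d])
    R = vt.T @ D @ u.T
    t = cb - R @ ca
    fitted = a @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    fit_selection=None,
    measure_selection=None,
) -> np.ndarray:
    """Per-frame RMSD after superposing each frame onto the reference.

    The reference defaults to frame 0 (deviation relative to the initial
    structure); the fit selection defaults to the protein backbone, and the
    RMSD is measured over ``measure_selection`` (defaults to the fit
    selection) after applying the fitted transform to the whole frame.
    """
    if fit_selection is None:
        fit_selection = "protein and backbone"
    fit_idx = _resolve(traj, fit_selection)
    measure_idx = fit_idx if measure_selection is None else _resolve(traj, measure_selection)
    if measure_idx.size == 0:
        raise ValueError("empty measure selection")
    ref = traj.coords[0] if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("reference must match the trajectory's atom count")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(traj.coords[f], ref, fit_idx)
        moved = traj.coords[f][measure_idx] @ R.T + t
        out[f] = np.sqrt(np.mean(np.sum((moved - ref[measure_idx]) ** 2, axis=1)))
    return out


def radius_of_gyration(traj: Trajectory, selection=None, mass_weighted: bool = True) -> np.ndarray:
    """Per-frame radius of gyration over a selection:
    ``Rg = sqrt(Σ wᵢ|rᵢ − r̄|² / Σ wᵢ)`` with mass weights by default."""
    idx = _resolve(traj, selection)
    if idx.size == 0:
        raise ValueError("empty selection")
    if mass_weighted:
        w = traj.atoms["mass"].to_numpy()[idx]
        if w.sum() <= 0:
            raise ValueError("zero total mass in selection")
    else:
        w = np.ones(idx.size)
    xyz = traj.coords[:, idx, :]
    center = (xyz * w[None, :, None]).sum(axis=1) / w.sum()
    d2 = np.sum((xyz - center[:, None, :]) ** 2, axis=2)
    return np.sqrt((d2 * w[None, :]).sum(axis=1) / w.sum())


def _superpose_to_mean(coords: np.ndarray, fit_idx: np.ndarray, passes: int = 2) -> np.ndarray:
    """Iteratively fit all frames to their running mean structure (removes
    global rotation + translation)."""
    fitted = coords.copy()
    for _ in range(passes):
        mean = fitted.mean(axis=0)
        for f in range(fitted.shape[0]):
            R, t, _ = kabsch_superpose(fitted[f], mean, fit_idx)
            fitted[f] = fitted[f] @ R.T + t
    return fitted


def rmsf(traj: Trajectory, selection=None, fit: bool = True):
    """Per-atom RMSF about the mean structure, optionally after removing
    global motion by iterative superposition (default on).

    Returns ``(per_atom, per_residue)``: the per-atom values over the
    selection, and a dict residue_index → mean RMSF of its selected atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = _resolve(traj, selection)
    if idx.size == 0:
        raise ValueError("empty selection")
    coords = traj.coords
    if fit:
        coords = _superpose_to_mean(coords, idx)
    xyz = coords[:, idx, :]
    mean = xyz.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((xyz - mean[None]) ** 2, axis=2), axis=0))
    resids = traj.atoms["residue_index"].to_numpy()[idx]
    per_residue = {int(r): float(per_atom[resids == r].mean()) for r in np.unique(resids)}
    return per_atom, per_residue


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBondCriteria:
    """Geometric H-bond definition: donor-heavy-atom···acceptor distance
    cutoff (Å), D–H···A angle cutoff (degrees) and the occupancy fraction
    below which a bond is dropped from the headline table.  Comparisons at
    the cutoffs are inclusive."""

    distance_cutoff: float = 3.0
    angle_cutoff: float = 135.0
    occupancy_cutoff: float = 0.20

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.angle_cutoff <= 180:
            raise ValueError("angle cutoff must be in (0, 180]")
        if not 0 <= self.occupancy_cutoff <= 1:
            raise ValueError("occupancy cutoff must be a fraction")


@dataclass
class HBondStat:
    donor: int
    hydrogen: int
    acceptor: int
    occupancy: float  # percent of frames
    average_distance: float  # Å over satisfying frames (nan if never)
    label: str = ""


def _angle_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """D–H···A angle per frame, degrees."""
    v1 = d - h
    v2 = a - h
    num = np.sum(v1 * v2, axis=-1)
    den = np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
    cosang = np.clip(num / np.where(den == 0, np.inf, den), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def hbond_stats(
    traj: Trajectory,
    roster: list[tuple[int, int, int]],
    criteria: HBondCriteria | None = None,
):
    """Occupancy statistics for candidate hydrogen bonds.

    ``roster`` lists ``(donor, hydrogen, acceptor)`` atom-index triples;
    hydrogens must be explicit.  A frame satisfies a candidate iff the
    donor···acceptor distance is ≤ the distance cutoff and the D–H···A angle
    is ≥ the angle cutoff (both inclusive).

    Returns ``(headline, full, per_frame_counts)``: bonds at or above the
    occupancy cutoff, all bonds, and the number of satisfied candidates in
    each frame.
    """
    criteria = criteria or HBondCriteria()
    n_atoms = traj.n_atoms
    full: list[HBondStat] = []
    counts = np.zeros(traj.n_frames, dtype=int)
    names = traj.atoms["atom_name"]
    for donor, hydrogen, acceptor in roster:
        for i in (donor, hydrogen, acceptor):
            if not 0 <= i < n_atoms:
                raise ValueError(f"roster atom index {i} outside topology")
        if traj.atoms["element"].iloc[hydrogen] != "H":
            logger.warning("skipping candidate with non-hydrogen atom %d", hydrogen)
            continue
        d = traj.coords[:, donor, :]
        h = traj.coords[:, hydrogen, :]
        a = traj.coords[:, acceptor, :]
        dist = np.linalg.norm(d - a, axis=1)
        ang = _angle_deg(d, h, a)
        sat = (dist <= criteria.distance_cutoff) & (ang >= criteria.angle_cutoff)
        counts += sat
        occupancy = 100.0 * sat.mean()
        avg = float(dist[sat].mean()) if sat.any() else float("nan")
        label = f"{names.iloc[donor]}-{names.iloc[hydrogen]}...{names.iloc[acceptor]}"
        full.append(HBondStat(donor, hydrogen, acceptor, occupancy, avg, label))
    headline = [b for b in full if b.occupancy >= 100.0 * criteria.occupancy_cutoff]
    return headline, full, counts


# ---------------------------------------------------------------------------
# PCA and free-energy landscape
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending, Å²
    eigenvectors: np.ndarray  # (3N, n_components), columns
    projections: np.ndarray  # (F, n_components)
    variance_fractions: np.ndarray
    total_variance: float


def trajectory_pca(traj: Trajectory, selection=None, n_components: int | None = None) -> PCAResult:
    """Cartesian PCA of the selected atoms with global motion removed.

    Frames are iteratively superposed to the mean structure (two passes),
    the 3N-dimensional coordinate vectors are centred, and the covariance is
    eigendecomposed.  Eigenvalues are returned in descending order; the sum
    of all eigenvalues equals the total positional variance.
    """
    idx = _resolve(traj, selection)
    if idx.size == 0:
        raise ValueError("empty selection")
    if traj.n_frames <= 3 * idx.size:
        logger.warning(
            "only %d frames for %d coordinates; covariance will be rank-deficient",
            traj.n_frames,
            3 * idx.size,
        )
    coords = _superpose_to_mean(traj.coords, idx)
    flat = coords[:, idx, :].reshape(traj.n_frames, -1)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if n_components is not None:
        evals_kept = evals[:n_components]
        evecs = evecs[:, :n_components]
    else:
        evals_kept = evals
    projections = centered @ evecs
    total = float(np.trace(cov))
    fractions = evals_kept / total if total > 0 else np.zeros_like(evals_kept)
    return PCAResult(
        eigenvalues=evals_kept,
        eigenvectors=evecs,
        projections=projections,
        variance_fractions=fractions,
        total_variance=total,
    )


@dataclass
class FreeEnergySurface:
    """Boltzmann-inverted 2-D free-energy surface over (PC1, PC2).

    ``energy`` holds G in kcal/mol with the occupied minimum at 0; ``empty``
    marks bins with no frames, which carry the maximum finite G plus
    ``empty_offset``."""

    edges1: np.ndarray
    edges2: np.ndarray
    energy: np.ndarray
    empty: np.ndarray
    temperature: float
    unit: str = "kcal/mol"
    n_basins: int = 0
    counts: np.ndarray = field(default=None, repr=False)


def free_energy_landscape(
    pc1: np.ndarray,
    pc2: np.ndarray,
    bins: int = 32,
    temperature: float = 300.0,
    unit: str = "kcal/mol",
    empty_offset: float = 1.0,
    basin_depth: float = 0.5,
) -> FreeEnergySurface:
    """Free-energy landscape ``G = −k_B·T·ln(n_bin / n_max)`` over PC1/PC2.

    At 300 K, k_B·T ≈ 0.596 kcal/mol, so two bins whose populations differ
    by a factor of e differ by exactly one k_B·T.  Empty bins are assigned
    the maximum finite G plus ``empty_offset`` and flagged.  ``n_basins``
    counts local minima deeper than ``basin_depth`` below their 8-neighbour
    rim.
    """
    pc1 = np.asarray(pc1, dtype=float).ravel()
    pc2 = np.asarray(pc2, dtype=float).ravel()
    if pc1.size == 0 or pc1.size != pc2.size:
        raise ValueError("PC1/PC2 projections must be equal-length and non-empty")
    kt = KB_KCAL * temperature
    if unit == "kJ/mol":
        kt *= 4.184
    elif unit != "kcal/mol":
        raise ValueError("unit must be kcal/mol or kJ/mol")
    counts, e1, e2 = np.histogram2d(pc1, pc2, bins=bins)
    occupied = counts > 0
    if not occupied.any():
        raise ValueError("no occupied bins")
    energy = np.full_like(counts, np.nan)
    energy[occupied] = -kt * np.log(counts[occupied] / counts.max())
    gmax = float(np.nanmax(energy))
    empty = ~occupied
    energy[empty] = gmax + empty_offset
    n_basins = _count_basins(energy, occupied, basin_depth)
    return FreeEnergySurface(
        edges1=e1,
        edges2=e2,
        energy=energy,
        empty=empty,
        temperature=temperature,
        unit=unit,
        n_basins=n_basins,
        counts=counts,
    )


def _count_basins(energy: np.ndarray, occupied: np.ndarray, depth: float) -> int:
    """Local minima over occupied bins whose 8-neighbourhood rim lies at
    least ``depth`` above them."""
    n1, n2 = energy.shape
    basins = 0
    for i in range(n1):
        for j in range(n2):
            if not occupied[i, j]:
                continue
            g = energy[i, j]
            neigh = [
                energy[x, y]
                for x in range(max(0, i - 1), min(n1, i + 2))
                for y in range(max(0, j - 1), min(n2, j + 2))
                if (x, y) != (i, j)
            ]
            if neigh and all(v >= g + depth for v in neigh):
                basins += 1
    return basins


def binding_site_selection(
    traj: Trajectory,
    ligand_selection="ligand",
    cutoff: float = 5.0,
    frame: int = 0,
    backbone_only: bool = True,
) -> AtomSelection:
    """Protein residues with any heavy atom within ``cutoff`` Å (inclusive)
    of any ligand heavy atom in the given frame; the returned selection is
    those residues' backbone atoms by default."""
    lig_idx = _resolve(traj, ligand_selection)
    if lig_idx.size == 0:
        raise ValueError("empty ligand selection")
    atoms = traj.atoms
    heavy = (atoms["element"] != "H").to_numpy()
    prot = (atoms["chain"] == "protein").to_numpy() & heavy
    lig_heavy = np.array([i for i in lig_idx if heavy[i]], dtype=int)
    prot_idx = np.flatnonzero(prot)
    if lig_heavy.size == 0 or prot_idx.size == 0:
        return AtomSelection(indices=np.array([], dtype=int), definition="binding_site")
    xyz = traj.coords[frame]
    d = np.linalg.norm(xyz[prot_idx][:, None, :] - xyz[lig_heavy][None, :, :], axis=2)
    close = prot_idx[(d <= cutoff).any(axis=1)]
    residues = np.unique(atoms["residue_index"].to_numpy()[close])
    if residues.size == 0:
        logger.warning("no protein residues within %.1f Å of the ligand", cutoff)
        return AtomSelection(indices=np.array([], dtype=int), definition="binding_site")
    in_res = atoms["residue_index"].isin(residues).to_numpy() & (atoms["chain"] == "protein").to_numpy()
    if backbone_only:
        in_res &= atoms["backbone"].to_numpy()
    return AtomSelection(indices=np.flatnonzero(in_res), definition=f"binding_site<= {cutoff} A")
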