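"""Substrate featurization: the five representations and 3D steric descriptors.

Five substrate representations are compared for modelling a transaminase
panel: one-hot encoding (OHE), Morgan fingerprints (fp), RDKit
physicochemical descriptors (phys), quantum-chemical descriptors ingested
from an Auto-QChem-style table (DFT), and phys+DFT.  The DFT table is
completed with in-package 3D steric descriptors computed from conformer
ensembles: Sterimol L/B1/B5 down the two carbonyl->alpha bonds and percent
buried volume (V_bur) at each alpha carbon, Boltzmann-averaged over the
ensemble.  Because the two alpha carbons of an unsymmetrical ketone are not
interchangeable, they are relabelled "large"/"small" by their relative V_bur
so that columns mean the same thing across substrates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import R_KCAL, covalent_radius, vdw_radius
from .io import (
    ConformerEnsemble,
    FeatureTable,
    QMFeatures,
    SubstrateRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_BOLTZMANN_T = 298.15   # K
VBUR_SPHERE_RADIUS = 3.5       # angstrom
VBUR_RADII_SCALE = 1.17        # Bondi radii scaling, common catalysis practice
VBUR_GRID_STEP = 0.05          # angstrom
BOND_TOLERANCE = 1.3           # bond if d < tol * (r_cov_i + r_cov_j)


# ---------------------------------------------------------------------------
# Simple featurizations
# ---------------------------------------------------------------------------

def build_ohe(substrate_ids: Sequence[str]) -> FeatureTable:
    """Identity-patterned one-hot table; an unseen id maps to an all-zero row.

    OHE carries no chemistry, so models built on it cannot generalize to new
    substrates — it serves as the near-random baseline featurization.
    """
    ids = list(substrate_ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("substrate ids must be unique")
    df = pd.DataFrame(np.eye(len(ids)), index=ids, columns=[f"is_{s}" for s in ids])
    return FeatureTable(df, "OHE")


def ohe_row(table: FeatureTable, substrate_id: str) -> np.ndarray:
    """Encoding of one substrate against an OHE table; a substrate the table
    has never seen maps to the all-zero row (OHE cannot generalize — that is
    the point of the baseline)."""
    if table.tag != "OHE":
        raise ValueError("ohe_row applies to OHE tables only")
    if substrate_id in table.df.index:
        return table.df.loc[substrate_id].to_numpy(dtype=float)
    return np.zeros(len(table.feature_names))


def compute_fingerprint(smiles: str, radius: int = 2, nbits: int = 2048) -> np.ndarray:
    """Morgan fingerprint as a {0,1} vector; deterministic for identical input."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES {smiles!r} does not parse")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(nbits, dtype=np.int8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def build_fp_table(
    substrates: Sequence[SubstrateRecord], radius: int = 2, nbits: int = 2048
) -> FeatureTable:
    rows = {
        s.substrate_id: compute_fingerprint(s.smiles, radius, nbits) for s in substrates
    }
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = [f"fp_{i}" for i in range(nbits)]
    return FeatureTable(_drop_uninformative(df, "fp"), "fp")


def compute_physchem(smiles: str) -> dict[str, float]:
    """Full RDKit physicochemical descriptor set for one molecule."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES {smiles!r} does not parse")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        values = Descriptors.CalcMolDescriptors(mol)
    return {k: float(v) for k, v in values.items()}


def build_phys_table(substrates: Sequence[SubstrateRecord]) -> FeatureTable:
    rows = {s.substrate_id: compute_physchem(s.smiles) for s in substrates}
    df = pd.DataFrame.from_dict(rows, orient="index")
    return FeatureTable(_drop_uninformative(df, "phys"), "phys")


def _drop_uninformative(df: pd.DataFrame, tag: str) -> pd.DataFrame:
    """Drop all-NaN, any-non-finite and constant-across-dataset columns."""
    values = df.to_numpy(dtype=float)
    finite = np.isfinite(values).all(axis=0)
    constant = np.zeros(df.shape[1], dtype=bool)
    constant[finite] = np.ptp(values[:, finite], axis=0) == 0 if df.shape[0] > 1 else False
    keep = finite & ~constant
    dropped = [c for c, k in zip(df.columns, keep) if not k]
    if dropped:
        logger.info("%s table: dropped %d uninformative column(s): %s",
                    tag, len(dropped), dropped[:20])
    return df.loc[:, keep]


# ---------------------------------------------------------------------------
# Boltzmann averaging
# ---------------------------------------------------------------------------

def boltzmann_weights(
    relative_energies: Sequence[float], temperature: float = DEFAULT_BOLTZMANN_T
) -> np.ndarray:
    """Conformer population weights w_i = exp(-E_i/RT) / sum_j exp(-E_j/RT)."""
    energies = np.asarray(relative_energies, dtype=float)
    if energies.size == 0:
        raise ValueError("empty energy list")
    if not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    if abs(energies.min()) > 1e-9:
        raise ValueError("relative energies must have minimum 0")
    w = np.exp(-energies / (R_KCAL * temperature))
    return w / w.sum()


def boltzmann_average(
    per_conformer_values: Sequence[np.ndarray] | Sequence[Sequence[float]],
    weights: Sequence[float],
) -> np.ndarray:
    """Elementwise population-weighted mean of per-conformer feature vectors."""
    values = np.asarray(per_conformer_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if values.shape[0] != w.shape[0]:
        raise ValueError(
            f"{values.shape[0]} value vectors but {w.shape[0]} weights"
        )
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return np.tensordot(w, values, axes=1)


# ---------------------------------------------------------------------------
# Connectivity (distance-based, for XYZ geometries without bond records)
# ---------------------------------------------------------------------------

def infer_bonds(elements: Sequence[str], coords: np.ndarray) -> list[set[int]]:
    """Adjacency list from covalent radii: bonded if d < 1.3 (r_i + r_j)."""
    n = len(elements)
    radii = np.array([covalent_radius(e) for e in elements])
    adjacency: list[set[int]] = [set() for _ in range(n)]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    cutoff = BOND_TOLERANCE * (radii[:, None] + radii[None, :])
    bonded = (dist < cutoff) & ~np.eye(n, dtype=bool)
    for i, j in zip(*np.where(bonded)):
        adjacency[i].add(int(j))
    return adjacency


def _reachable(adjacency: list[set[int]], start: int, blocked: int) -> set[int]:
    """Atoms reachable from `start` without passing through `blocked`."""
    seen = {start}
    stack = [start]
    while stack:
        a = stack.pop()
        for b in adjacency[a]:
            if b != blocked and b not in seen:
                seen.add(b)
                stack.append(b)
    return seen


# ---------------------------------------------------------------------------
# Sterimol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SterimolValues:
    """Verloop steric parameters of a substituent (angstrom).

    L: extent along the attachment axis, measured from the dummy atom.
    B1/B5: minimum/maximum perpendicular half-width.  Built from Bondi radii.
    """

    L: float
    B1: float
    B5: float

    def __post_init__(self) -> None:
        if not (self.B1 <= self.B5 + 1e-9):
            raise ValueError(f"B1 ({self.B1}) must be <= B5 ({self.B5})")
        if min(self.L, self.B1, self.B5) <= 0:
            raise ValueError("Sterimol values must be positive")


def compute_sterimol(
    elements: Sequence[str],
    coords: np.ndarray,
    dummy_atom: int,
    attached_atom: int,
    scan_step_deg: float = 1.0,
) -> SterimolValues:
    """Sterimol L/B1/B5 of the substituent rooted at `attached_atom`.

    The axis is the unit vector dummy -> attached (here: carbonyl C -> alpha
    C).  The substituent is every atom reachable from the attached atom
    without crossing the dummy atom.  L is the maximal projection onto the
    axis measured from the dummy atom plus the atom's vdW radius; B5 is the
    maximal perpendicular extent; B1 minimizes, over perpendicular directions
    scanned at `scan_step_deg` resolution, the maximal extent along that
    direction.
    """
    coords = np.asarray(coords, dtype=float)
    adjacency = infer_bonds(elements, coords)
    if attached_atom not in adjacency[dummy_atom]:
        raise ValueError(
            f"atoms {dummy_atom} and {attached_atom} are not bonded in this geometry"
        )
    substituent = sorted(_reachable(adjacency, attached_atom, blocked=dummy_atom))
    if not substituent:
        raise ValueError("substituent atom set is empty")

    origin = coords[dummy_atom]
    axis = coords[attached_atom] - origin
    axis = axis / np.linalg.norm(axis)

    rel = coords[substituent] - origin
    radii = np.array([vdw_radius(elements[a]) for a in substituent])
    proj = rel @ axis
    L = float(np.max(proj + radii))

    perp = rel - np.outer(proj, axis)
    perp_norm = np.linalg.norm(perp, axis=1)
    B5 = float(np.max(perp_norm + radii))

    # orthonormal frame for the perpendicular plane, anchored to the molecule
    # (the B5 atom's perpendicular direction) so the 1-degree scan co-rotates
    # with the geometry and B1 is rigid-motion invariant
    anchor = int(np.argmax(perp_norm))
    if perp_norm[anchor] > 1e-8:
        e1 = perp[anchor] / perp_norm[anchor]
    else:
        seed = np.array([1.0, 0.0, 0.0])
        if abs(axis @ seed) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        e1 = seed - (seed @ axis) * axis
        e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    angles = np.deg2rad(np.arange(0.0, 360.0, scan_step_deg))
    directions = np.outer(np.cos(angles), e1) + np.outer(np.sin(angles), e2)
    # width along each direction: max over atoms of signed projection + radius
    widths = directions @ perp.T + radii[None, :]
    B1 = float(np.min(np.max(widths, axis=1)))
    return SterimolValues(L=L, B1=B1, B5=B5)


# ---------------------------------------------------------------------------
# Buried volume
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=4)
def _sphere_grid(sphere_radius: float, grid_step: float) -> np.ndarray:
    """Uniform grid points inside a sphere at the origin (cached)."""
    axes = np.arange(-sphere_radius, sphere_radius + grid_step / 2, grid_step)
    gx, gy, gz = np.meshgrid(axes, axes, axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.einsum("ij,ij->i", grid, grid) <= sphere_radius**2
    return grid[inside]


def compute_buried_volume(
    elements: Sequence[str],
    coords: np.ndarray,
    center_atom: int,
    sphere_radius: float = VBUR_SPHERE_RADIUS,
    radii_scale: float = VBUR_RADII_SCALE,
    grid_step: float = VBUR_GRID_STEP,
    exclude_atoms: Iterable[int] | None = None,
) -> float:
    """Fraction of a probe sphere at `center_atom` buried by vdW spheres.

    Uniform-grid integration over the sphere (default radius 3.5 angstrom,
    grid 0.05 angstrom, Bondi radii x 1.17, H atoms included).  The center
    atom itself is always excluded; `exclude_atoms` removes further atoms
    (the alpha-role protocol excludes the carbonyl side so each alpha carbon
    is scored on its own substituent only).
    """
    coords = np.asarray(coords, dtype=float)
    if not 0 <= center_atom < len(coords):
        raise ValueError(f"center atom {center_atom} out of range")
    excluded = {center_atom} | set(exclude_atoms or ())
    included = [a for a in range(len(coords)) if a not in excluded]

    center = coords[center_atom]
    grid = _sphere_grid(float(sphere_radius), float(grid_step)) + center
    n_total = grid.shape[0]

    occupied = np.zeros(n_total, dtype=bool)
    any_atom_near = False
    for a in included:
        r = vdw_radius(elements[a]) * radii_scale
        d = coords[a] - center
        if np.linalg.norm(d) > sphere_radius + r:
            continue
        any_atom_near = True
        delta = grid - coords[a]
        occupied |= np.einsum("ij,ij->i", delta, delta) <= r * r
    if not any_atom_near:
        warnings.warn(
            f"no atoms intersect the probe sphere at atom {center_atom}; V_bur = 0"
        )
        return 0.0
    return float(occupied.sum() / n_total)


@dataclass(frozen=True)
class AlphaRoleAssignment:
    """Which alpha carbon is the "large" and which the "small" substituent side."""

    large_alpha_index: int
    small_alpha_index: int
    vbur_large: float
    vbur_small: float

    def __post_init__(self) -> None:
        if self.vbur_large < self.vbur_small - 1e-12:
            raise ValueError("vbur_large must be >= vbur_small")


def assign_alpha_roles(
    substrate: SubstrateRecord,
    ensemble: ConformerEnsemble,
    temperature: float = DEFAULT_BOLTZMANN_T,
    tie_tolerance: float = 1e-6,
    **vbur_kwargs,
) -> AlphaRoleAssignment:
    """Label the two alpha carbons large/small by ensemble-averaged V_bur.

    V_bur is evaluated at each alpha carbon on every conformer, scoring only
    that alpha's own substituent atoms (the center atom and everything on the
    carbonyl side are excluded), then Boltzmann-weight averaged.  Ties within
    `tie_tolerance` break to the lower atom index with a warning — only the
    relative ordering is consumed downstream.
    """
    if substrate.alpha_atom_indices is None or substrate.carbonyl_atom_index is None:
        raise ValueError(
            f"substrate {substrate.substrate_id!r}: reaction-site atom indices required"
        )
    a1, a2 = substrate.alpha_atom_indices
    if a1 == a2:
        raise ValueError("two distinct alpha carbons required (aldehydes unsupported)")
    carbonyl = substrate.carbonyl_atom_index

    weights = boltzmann_weights(ensemble.energies, temperature)
    vburs = {}
    for alpha in (a1, a2):
        per_conf = []
        for coords in ensemble.coordinates:
            adjacency = infer_bonds(ensemble.elements, coords)
            if alpha not in adjacency[carbonyl]:
                raise ValueError(
                    f"substrate {substrate.substrate_id!r}: atom {alpha} is not "
                    f"bonded to the carbonyl carbon {carbonyl}"
                )
            carbonyl_side = _reachable(adjacency, carbonyl, blocked=alpha)
            per_conf.append(
                compute_buried_volume(
                    ensemble.elements,
                    coords,
                    center_atom=alpha,
                    exclude_atoms=carbonyl_side,
                    **vbur_kwargs,
                )
            )
        vburs[alpha] = float(np.dot(weights, per_conf))

    lo, hi = sorted((a1, a2))
    if abs(vburs[a1] - vburs[a2]) <= tie_tolerance:
        warnings.warn(
            f"substrate {substrate.substrate_id!r}: alpha V_bur tie "
            f"({vburs[a1]:.6f} vs {vburs[a2]:.6f}); assigning large to lower "
            f"atom index {lo}"
        )
        large, small = lo, hi
    elif vburs[a1] > vburs[a2]:
        large, small = a1, a2
    else:
        large, small = a2, a1
    return AlphaRoleAssignment(
        large_alpha_index=large,
        small_alpha_index=small,
        vbur_large=vburs[large],
        vbur_small=vburs[small],
    )


def boltzmann_averaged_sterimol(
    substrate: SubstrateRecord,
    ensemble: ConformerEnsemble,
    alpha_atom: int,
    temperature: float = DEFAULT_BOLTZMANN_T,
) -> SterimolValues:
    """Per-conformer Sterimol down carbonyl->alpha, then population-averaged."""
    weights = boltzmann_weights(ensemble.energies, temperature)
    values = np.array(
        [
            [s.L, s.B1, s.B5]
            for s in (
                compute_sterimol(
                    ensemble.elements,
                    coords,
                    dummy_atom=substrate.carbonyl_atom_index,
                    attached_atom=alpha_atom,
                )
                for coords in ensemble.coordinates
            )
        ]
    )
    L, B1, B5 = boltzmann_average(values, weights)
    return SterimolValues(L=float(L), B1=float(B1), B5=float(B5))


# ---------------------------------------------------------------------------
# DFT table assembly
# ---------------------------------------------------------------------------

def assemble_dft_features(
    qm: Mapping[str, QMFeatures],
    substrates: Sequence[SubstrateRecord],
    assignments: Mapping[str, AlphaRoleAssignment],
    sterimol: Mapping[str, Mapping[str, SterimolValues]],
) -> FeatureTable:
    """Build the DFT feature table: one row per substrate.

    Layout per row (deterministic order): molecule-level features, carbonyl-
    atom features (prefix ``carbonyl_``), alpha-atom features relabelled by
    role (prefixes ``alpha_large_``/``alpha_small_``), then Sterimol L/B1/B5
    per role.  `sterimol[sid]` maps role ("large"/"small") to values.
    Swapping the raw order of the two alpha atoms leaves the table unchanged
    because columns are keyed by role, not by atom index.
    """
    rows: dict[str, dict[str, float]] = {}
    for sub in substrates:
        sid = sub.substrate_id
        if sid not in qm:
            raise ValidationError(f"substrate {sid!r}: no QM features available")
        feats = qm[sid]
        assignment = assignments[sid]
        row: dict[str, float] = {}
        for name in sorted(feats.molecule):
            row[name] = feats.molecule[name]
        for prefix, atom in (
            ("carbonyl_", sub.carbonyl_atom_index),
            ("alpha_large_", assignment.large_alpha_index),
            ("alpha_small_", assignment.small_alpha_index),
        ):
            if atom not in feats.atoms:
                raise ValidationError(
                    f"substrate {sid!r}: missing atom-level QM features for "
                    f"reaction-site atom {atom}"
                )
            for name in sorted(feats.atoms[atom]):
                row[prefix + name] = feats.atoms[atom][name]
        for role in ("large", "small"):
            sv = sterimol[sid][role]
            row[f"sterimol_{role}_L"] = sv.L
            row[f"sterimol_{role}_B1"] = sv.B1
            row[f"sterimol_{role}_B5"] = sv.B5
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.loc[[s.substrate_id for s in substrates]]
    return FeatureTable(_drop_uninformative(df, "DFT"), "DFT")
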