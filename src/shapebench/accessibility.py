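"""Per-residue solvent-accessible surface area (SASA) and the
accessibility filter for in vivo ROC evaluation.

SASA is computed with the Shrake-Rupley method: each atom's sphere is
expanded by the probe radius and sampled with a deterministic
golden-angle spiral lattice; the accessible fraction is the fraction of
test points outside every neighboring expanded sphere.  The probe radius
defaults to 3.0 Å (sized to the probing reagent rather than to water)
and residues with SASA strictly greater than 2.0 Å² count as accessible.
Absolute SASA values depend on the van der Waals radius table, so the
accessible *set* (with a configurable threshold), not raw SASA, is the
interface to the ROC step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .formats import ResidueCoordinates

__all__ = ["ResidueSASA", "shrake_rupley", "accessible_residues", "sphere_points"]


@dataclass(frozen=True)
class ResidueSASA:
    chain: str
    resnum: int
    sasa: float  # Å², non-negative


def sphere_points(n_points: int, seed=None) -> np.ndarray:
    """Unit-sphere test points.

    Default is the deterministic golden-angle (Fibonacci) spiral lattice;
    if ``seed`` is given, points are drawn uniformly at random instead
    (useful as an independent sampling scheme in convergence checks).
    """
    if seed is not None:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(n_points, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    k = np.arange(n_points, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(residues: list[ResidueCoordinates], probe_radius: float = 3.0,
                  n_points: int = 2048, seed=None,
                  brute_force: bool = False) -> list[ResidueSASA]:
    """Per-residue SASA by Shrake-Rupley point sampling.

    Per atom: SASA = 4*pi*(r+probe)^2 * (fraction of test points not inside
    any neighbor's probe-expanded sphere); per residue: sum over its atoms.
    ``brute_force=True`` checks every atom pair instead of using the
    KD-tree neighbor search (testing fallback).
    """
    if not residues:
        raise ValueError("no residues given")
    coords = np.concatenate([r.coords() for r in residues], axis=0)
    radii = np.concatenate([r.radii() for r in residues], axis=0)
    if np.any(radii <= 0):
        raise ValueError("every atom needs a positive van der Waals radius")
    owner = np.concatenate([
        np.full(len(r.atoms), k, dtype=np.int64) for k, r in enumerate(residues)
    ])
    expanded = radii + probe_radius
    points = sphere_points(n_points, seed=seed)
    n_atoms = len(coords)

    if brute_force:
        neighbor_lists = [
            [j for j in range(n_atoms) if j != i
             and np.linalg.norm(coords[i] - coords[j]) < expanded[i] + expanded[j]]
            for i in range(n_atoms)
        ]
    else:
        tree = cKDTree(coords)
        rmax = float(expanded.max())
        neighbor_lists = []
        for i in range(n_atoms):
            cand = tree.query_ball_point(coords[i], expanded[i] + rmax)
            neighbor_lists.append([
                j for j in cand if j != i
                and np.linalg.norm(coords[i] - coords[j]) < expanded[i] + expanded[j]
            ])

    per_residue = np.zeros(len(residues))
    for i in range(n_atoms):
        test = coords[i] + expanded[i] * points
        free = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            d2 = np.sum((test - coords[j]) ** 2, axis=1)
            free &= d2 >= expanded[j] ** 2
            if not free.any():
                break
        area = 4.0 * np.pi * expanded[i] ** 2 * free.mean()
        per_residue[owner[i]] += area
    return [ResidueSASA(chain=r.chain, resnum=r.resnum, sasa=float(per_residue[k]))
            for k, r in enumerate(residues)]


def accessible_residues(sasa_list: list[ResidueSASA],
                        threshold: float = 2.0) -> set[tuple[str, int]]:
    """Residues with SASA strictly greater than ``threshold`` (Å²)."""
    return {(r.chain, r.resnum) for r in sasa_list if r.sasa > threshold}
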