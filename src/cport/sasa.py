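"""Solvent-accessible surface area by the Shrake-Rupley method.

Each atom is inflated by the probe radius and covered with a
quasi-uniform point mesh (golden-spiral lattice); the accessible area is
the fraction of points not inside any neighbouring inflated atom, times
the sphere area.  960 points per atom keep the per-atom quadrature
error well under the 15% accessibility threshold this package uses.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_PROBE = 1.4  # water probe radius, Angstrom
DEFAULT_N_POINTS = 960

#: Van der Waals radii (Angstrom) by element; the fallback covers
#: uncommon heteroelements conservatively.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.80


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral lattice of n quasi-uniform points on the unit sphere."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def atom_radii(elements: np.ndarray) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e).upper(), DEFAULT_RADIUS) for e in elements])


def shrake_rupley(
    coords: np.ndarray,
    elements: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area in square Angstrom.

    Parameters
    ----------
    coords : (n_atoms, 3) array of coordinates in Angstrom.
    elements : (n_atoms,) array of element symbols.
    probe : probe sphere radius; 0 gives the van-der-Waals surface.
    n_points : test points per atom sphere.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an (n, 3) array")
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    radii = atom_radii(np.asarray(elements)) + probe
    mesh = _sphere_points(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * mesh
        # neighbours whose inflated sphere could cover any test point
        neigh = tree.query_ball_point(coords[i], radii[i] + max_r)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas
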