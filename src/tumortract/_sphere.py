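"""Tessellated unit spheres for sampling orientation distribution functions.

The reconstruction evaluates the spin-distribution function on the vertices
of a subdivided icosahedron.  Icosahedral tessellations are antipodally
symmetric (the icosahedron is centrally symmetric and subdivision preserves
this), which the peak extractor relies on when it merges antipodal maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import trimesh


@dataclass(frozen=True)
class Sphere:
    """A triangulated unit sphere.

    Attributes
    ----------
    vertices : (V, 3) float array of unit vectors.
    faces : (F, 3) int array of triangle vertex indices.
    neighbors : tuple of int tuples, vertex adjacency from the edge graph.
    """

    vertices: np.ndarray
    faces: np.ndarray
    neighbors: tuple = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@lru_cache(maxsize=8)
def icosphere(subdivisions: int = 3) -> Sphere:
    """Subdivided icosahedron with unit-norm vertices.

    ``subdivisions=3`` gives 642 vertices (321 antipodal pairs), an angular
    vertex spacing of about 7 degrees; peak directions are refined below the
    vertex spacing by local quadratic interpolation in
    :func:`tumortract.recon.extract_peaks`.
    """
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    neighbors = tuple(tuple(nb) for nb in mesh.vertex_neighbors)
    return Sphere(vertices=vertices, faces=np.asarray(mesh.faces), neighbors=neighbors)


def tangent_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``direction`` and to each other."""
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2
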