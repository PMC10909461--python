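"""Isoparametric shape functions and quadrature for the element library.

Bulk elements are bilinear quadrilaterals (plane strain) and trilinear
hexahedra.  Nearly incompressible response uses selective reduced
integration: the isochoric part of the energy at the full Gauss rule, the
volumetric part at the element centroid.
"""

from __future__ import annotations

import numpy as np

_G = 1.0 / np.sqrt(3.0)


def quad4_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """N (4,) and dN/dxi (4,2) of the bilinear quadrilateral."""
    x, y = xi
    N = 0.25 * np.array([(1 - x) * (1 - y), (1 + x) * (1 - y),
                         (1 + x) * (1 + y), (1 - x) * (1 + y)])
    dN = 0.25 * np.array([
        [-(1 - y), -(1 - x)],
        [(1 - y), -(1 + x)],
        [(1 + y), (1 + x)],
        [-(1 + y), (1 - x)],
    ])
    return N, dN


def hex8_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """N (8,) and dN/dxi (8,3) of the trilinear hexahedron."""
    x, y, z = xi
    signs = np.array([
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ], dtype=float)
    sx, sy, sz = signs.T
    N = 0.125 * (1 + sx * x) * (1 + sy * y) * (1 + sz * z)
    dN = 0.125 * np.stack([
        sx * (1 + sy * y) * (1 + sz * z),
        (1 + sx * x) * sy * (1 + sz * z),
        (1 + sx * x) * (1 + sy * y) * sz,
    ], axis=1)
    return N, dN


def bulk_quadrature(elem_type: str):
    """(points, weights) of the full rule and the single-point rule."""
    if elem_type == "quad4":
        pts = np.array([[-_G, -_G], [_G, -_G], [_G, _G], [-_G, _G]])
        w = np.ones(4)
        return (pts, w), (np.zeros((1, 2)), np.array([4.0]))
    if elem_type == "hex8":
        pts = np.array([[sx * _G, sy * _G, sz * _G]
                        for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
        w = np.ones(8)
        return (pts, w), (np.zeros((1, 3)), np.array([8.0]))
    raise ValueError(f"unknown element type {elem_type!r}")


def shape_fn(elem_type: str):
    return {"quad4": quad4_shape, "hex8": hex8_shape}[elem_type]


def line2_quadrature():
    """2-point Gauss rule on [-1, 1] for line facets/interfaces."""
    pts = np.array([-_G, _G])
    w = np.ones(2)
    return pts, w


def line2_shape(xi: float) -> np.ndarray:
    return np.array([0.5 * (1 - xi), 0.5 * (1 + xi)])


def quad_facet_quadrature():
    """2x2 Gauss rule on the reference quadrilateral facet."""
    pts = np.array([[-_G, -_G], [_G, -_G], [_G, _G], [-_G, _G]])
    w = np.ones(4)
    return pts, w
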