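"""Mesh containers and structured mesh generation.

Meshes are plain arrays: nodes in mm, bulk connectivity with a material tag
per element, and an optional set of zero-thickness interface elements given
as pairs of coincident facets (bottom facet nodes followed by top facet
nodes).  The interface normal points from the bottom side to the top side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Mesh:
    """Unstructured mesh of a single bulk element type.

    nodes     : (nn, dim) coordinates, mm
    elems     : (ne, nen) connectivity (quad4: 4, hex8: 8)
    mat_id    : (ne,) index into the model's material list
    elem_type : "quad4" (plane strain) or "hex8"
    """

    nodes: np.ndarray
    elems: np.ndarray
    mat_id: np.ndarray
    elem_type: str

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_dofs(self) -> int:
        return self.n_nodes * self.dim

    def nodes_where(self, fn) -> np.ndarray:
        """Indices of nodes whose coordinates satisfy the predicate."""
        return np.flatnonzero(fn(self.nodes))


@dataclass
class InterfaceSet:
    """Zero-thickness cohesive interface elements.

    pairs  : (ni, 2*m) node indices: bottom facet then top facet
             (m = 2 line facets in 2D, m = 4 quad facets in 3D)
    torn   : (ni,) flags for elements inside the pre-existing tear; torn
             elements carry no cohesive stiffness but keep the contact
    s_hint : (ni, 3) reference direction of the mode-II (sliding) axis;
             the in-plane component orthogonal to it is the mode-III axis
    """

    pairs: np.ndarray
    torn: np.ndarray
    s_hint: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: 2D meshes only: whether in-plane sliding is mode II ("s") or III ("t")
    tangent_mode: str = "s"
    #: optional per-element front labels ("axial" | "circumferential")
    labels: np.ndarray | None = None

    def __post_init__(self):
        if self.s_hint is None:
            ni = self.pairs.shape[0]
            self.s_hint = np.tile(np.array([1.0, 0.0, 0.0]), (ni, 1))

    @property
    def n(self) -> int:
        return self.pairs.shape[0]

    @property
    def m(self) -> int:
        return self.pairs.shape[1] // 2


def _grid_nodes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    X, Y = np.meshgrid(x, y, indexing="xy")
    return np.column_stack([X.ravel(), Y.ravel()])


def _grid_quads(nx: int, ny: int, offset: int = 0) -> np.ndarray:
    """Counterclockwise quad connectivity of an (nx, ny)-cell grid."""
    e = []
    for j in range(ny):
        for i in range(nx):
            n0 = offset + j * (nx + 1) + i
            e.append([n0, n0 + 1, n0 + nx + 2, n0 + nx + 1])
    return np.array(e, dtype=int)


def rect_with_interface(Lx: float, Ly: float, nx: int, ny_bot: int, ny_top: int,
                        y_interface: float,
                        torn_until_x: float | None = None,
                        grade_bot: float = 1.0,
                        grade_top: float = 1.0):
    """Rectangular plane-strain strip with a horizontal cohesive interface.

    The strip occupies [0, Lx] x [0, Ly] with duplicated nodes along
    ``y = y_interface``; the interface normal points upward (+y).  Elements
    with centroid x < ``torn_until_x`` are flagged as pre-torn (an initial
    crack).  ``grade_*`` biases the through-thickness node spacing toward
    the interface (1 = uniform).

    Returns (mesh, interface, bottom_edge_nodes, top_edge_nodes) where the
    edge node arrays are the duplicated interface rows (useful for BCs).
    """
    if not 0 < y_interface < Ly:
        raise ValueError("interface must lie strictly inside the strip")
    x = np.linspace(0.0, Lx, nx + 1)

    def graded(a, b, n, g, toward_end):
        s = np.linspace(0.0, 1.0, n + 1) ** g
        s = s if toward_end else 1.0 - s[::-1]
        return a + (b - a) * s

    yb = graded(0.0, y_interface, ny_bot, grade_bot, toward_end=False)
    yt = graded(y_interface, Ly, ny_top, grade_top, toward_end=True)

    nodes_b = _grid_nodes(x, yb)
    nodes_t = _grid_nodes(x, yt)
    off = nodes_b.shape[0]
    nodes = np.vstack([nodes_b, nodes_t])
    elems = np.vstack([_grid_quads(nx, ny_bot, 0), _grid_quads(nx, ny_top, off)])
    mat_id = np.zeros(elems.shape[0], dtype=int)
    mesh = Mesh(nodes=nodes, elems=elems, mat_id=mat_id, elem_type="quad4")

    bot_row = np.arange(ny_bot * (nx + 1), (ny_bot + 1) * (nx + 1))
    top_row = off + np.arange(0, nx + 1)
    pairs = np.column_stack([bot_row[:-1], bot_row[1:], top_row[:-1], top_row[1:]])
    xc = 0.5 * (x[:-1] + x[1:])
    torn = np.zeros(nx, dtype=bool) if torn_until_x is None else xc < torn_until_x
    iface = InterfaceSet(pairs=pairs, torn=torn)
    return mesh, iface, bot_row, top_row
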