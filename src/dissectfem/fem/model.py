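"""Model, load schedule and result containers for the quasi-static solver."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ..cohesive import CohesiveParams
from ..hgo import MaterialParams
from .mesh import InterfaceSet, Mesh


@dataclass
class SolverControls:
    """Newton and load-stepping controls.

    Tolerances are on the residual force norm (mN), relative to a running
    reference of the internal/external force magnitude.
    """

    rtol: float = 1e-6
    #: absolute residual floor, mN: forces below this are negligible at the
    #: problem's mm/kPa scale
    atol: float = 1e-5
    max_iter: int = 25
    dgamma0: float = 0.05
    dgamma_min: float = 1e-5
    dgamma_max: float = 0.25
    grow: float = 1.4
    max_steps: int = 2000
    contact_penalty_factor: float = 10.0
    #: viscous regularization constant of the cohesive damage rate, in
    #: load-factor pseudo-time (0 = off); keeps softening steps solvable
    stabilization: float = 1e-3
    verbose: bool = False


@dataclass
class LoadStage:
    """One monotone ramp of the load factor gamma from 0 to 1.

    dirichlet : (dofs, values(gamma) -> array) prescribed displacements
    pressures : sequence of (facets, p(gamma) -> kPa) follower loads; facet
                node ordering makes the facet normal point outward from the
                solid into the pressurized fluid
    watch_failure : stop the ramp (and bisect) when an interface point
                fully fails
    gamma_resolution : bisection resolution on gamma for the failure event
    """

    dirichlet_dofs: np.ndarray
    dirichlet_vals: Callable[[float], np.ndarray]
    pressures: Sequence[tuple[np.ndarray, Callable[[float], float]]] = ()
    watch_failure: bool = False
    gamma_resolution: float = 1e-3
    name: str = "stage"


@dataclass
class FEModel:
    """Discretized boundary-value problem."""

    mesh: Mesh
    materials: Sequence[MaterialParams]
    interface: InterfaceSet | None = None
    cohesive: CohesiveParams | None = None
    stages: Sequence[LoadStage] = ()
    controls: SolverControls = field(default_factory=SolverControls)
    #: optional inverse prestrain gradient per bulk element (ne, 3, 3);
    #: the elastic deformation gradient is F_e = F @ Gpre
    Gpre: np.ndarray | None = None
    #: optional material frame per bulk element (ne, 3, 3); columns are the
    #: (circumferential, axial, radial) axes in global coordinates
    Qmat: np.ndarray | None = None

    def dof(self, nodes: np.ndarray, comp: int) -> np.ndarray:
        """Global dof indices of a component at the given nodes."""
        return np.asarray(nodes, dtype=int) * self.mesh.dim + comp


@dataclass
class StepRecord:
    """One converged equilibrium state of a ramp."""

    stage: str
    gamma: float
    u: np.ndarray
    iterations: int
    residual: float
    max_initiation: float
    max_failure: float
    external_work: float
    strain_energy: float
    cohesive_dissipation: float
    stabilization_energy: float


@dataclass
class Trajectory:
    """Sequence of converged states plus the final interface history."""

    records: list[StepRecord] = field(default_factory=list)
    completed: bool = True
    message: str = ""

    @property
    def final_u(self) -> np.ndarray:
        return self.records[-1].u

    def gamma_history(self) -> np.ndarray:
        return np.array([r.gamma for r in self.records])


@dataclass
class CriticalEvent:
    """First complete failure of a cohesive element under a pressure ramp."""

    Pc: float                      # true-lumen pressure at failure, kPa
    gamma: float                   # load factor at failure
    element: int                   # interface element index (first failed)
    elements: list[int]            # all elements failing in the same increment
    direction: str                 # "axial" | "circumferential" | "n/a"
    mode_mix: float                # m = 1 - G_I/G_T at the critical element
    Tn: float
    Ts: float
    Tt: float
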