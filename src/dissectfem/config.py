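"""Run configuration: a single YAML file with unit-suffixed keys.

All physical quantities carry their unit in the key name (..._kPa, ..._mm,
..._deg) to prevent unit drift.  An empty file yields the baseline study
configuration: tear eta = 150 deg, depth ratio t = 0.4, axial length
s = 10 mm, axial stretch 1.02, equal true/false lumen pressures, no
residual stress, and the bundled material/cohesive constants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cohesive import CohesiveParams
from .constants import ADVENTITIA, MEDIA, default_cohesive_params
from .hgo import MaterialParams


@dataclass
class GeometryConfig:
    Ri_mm: float = 7.5
    Ro_mm: float = 9.0
    media_fraction: float = 5.0 / 8.0
    eta_deg: float = 150.0
    s_mm: float = 10.0
    t_ratio: float = 0.4

    def validate(self):
        if not 0.0 < self.t_ratio < 1.0:
            raise ValueError("geometry.t_ratio must lie in (0, 1)")
        if not 0.0 < self.eta_deg <= 360.0:
            raise ValueError("geometry.eta_deg must lie in (0, 360]")
        if self.Ro_mm <= self.Ri_mm:
            raise ValueError("geometry.Ro_mm must exceed Ri_mm")


@dataclass
class MaterialConfig:
    media: dict = field(default_factory=lambda: _mat_dict(MEDIA))
    adventitia: dict = field(default_factory=lambda: _mat_dict(ADVENTITIA))

    def params(self) -> tuple[MaterialParams, MaterialParams]:
        return (_mat_from_dict(self.media), _mat_from_dict(self.adventitia))


@dataclass
class CohesiveConfig:
    TnC_kPa: float = 131.0
    TsC_kPa: float = 97.0
    TtC_kPa: float = 120.0
    GIC_mN_mm: float = 49.0
    GIIC_mN_mm: float = 200.0
    GIIIC_mN_mm: float = 240.0
    Kn_mN_mm3: float = 1638.0
    Ks_mN_mm3: float = 35000.0
    Kt_mN_mm3: float = 35000.0
    alpha: float = 1.0

    def params(self) -> CohesiveParams:
        return CohesiveParams(
            TnC=self.TnC_kPa, TsC=self.TsC_kPa, TtC=self.TtC_kPa,
            GIC=self.GIC_mN_mm, GIIC=self.GIIC_mN_mm, GIIIC=self.GIIIC_mN_mm,
            Kn=self.Kn_mN_mm3, Ks=self.Ks_mN_mm3, Kt=self.Kt_mN_mm3,
            alpha=self.alpha)


@dataclass
class LoadConfig:
    lambda_axial: float = 1.02
    p_TL_kPa: float = 200.0
    p_FL_kPa: float | None = None
    opening_angle_deg: float = 0.0

    def validate(self):
        if self.lambda_axial < 1.0:
            raise ValueError("load.lambda_axial must be >= 1")
        if self.p_TL_kPa < 0 or (self.p_FL_kPa is not None
                                 and self.p_FL_kPa < 0):
            raise ValueError("pressures must be non-negative")


@dataclass
class SolverConfig:
    n_theta: int = 36
    n_axial: int = 8
    n_r_inner: int = 1
    n_r_outer: int = 1
    n_r_adventitia: int = 1
    symmetry: str = "quarter"
    rtol: float = 1e-6
    stabilization: float = 1e-3
    pressure_resolution_kPa: float = 1.0


@dataclass
class OutputConfig:
    directory: str = "results"
    vtk: bool = True
    csv: bool = True


@dataclass
class RunConfig:
    """Full configuration of a tube run or sweep."""

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    cohesive: CohesiveConfig = field(default_factory=CohesiveConfig)
    load: LoadConfig = field(default_factory=LoadConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def validate(self) -> "RunConfig":
        self.geometry.validate()
        self.load.validate()
        self.cohesive.params()
        return self


_SECTIONS = {f.name: f.type for f in fields(RunConfig)}


def _mat_dict(p: MaterialParams) -> dict:
    return {"C10": p.C10, "k1_kPa": p.k1, "k2": p.k2, "kappa": p.kappa,
            "theta_deg": p.theta_deg, "D_per_kPa": p.D}


def _mat_from_dict(d: dict) -> MaterialParams:
    return MaterialParams(C10=d["C10"], k1=d["k1_kPa"], k2=d["k2"],
                          kappa=d["kappa"], theta_deg=d["theta_deg"],
                          D=d["D_per_kPa"])


def parse_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Unknown sections or keys are rejected with the offending name; missing
    entries fall back to the baseline defaults.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    cfg = RunConfig()
    for section, content in raw.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        target = getattr(cfg, section)
        known = {f.name for f in fields(target)}
        for key, value in (content or {}).items():
            if key not in known:
                raise ValueError(
                    f"unknown key {key!r} in section {section!r}")
            setattr(target, key, value)
    return cfg.validate()


def serialize_config(cfg: RunConfig) -> str:
    """YAML text with every effective value made explicit."""
    return yaml.safe_dump(asdict(cfg), sort_keys=True)
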