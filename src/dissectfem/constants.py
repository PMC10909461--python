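"""Bundled material and cohesive parameter sets for the human aortic wall.

Bulk constants come from biaxial testing of human thoracic aortic tissue
(Holzapfel--Gasser--Ogden model, one set per wall layer).  Cohesive
constants are the mode-I/II/III values calibrated against the peel,
direct-tension and shear delamination experiments of Sommer et al. on human
aortic media.

Units: stress kPa, energy per area mN/mm (= N/m), stiffness mN/mm^3,
angles degrees.
"""

from .hgo import MaterialParams


#: Medial layer of the human descending thoracic aorta.
MEDIA = MaterialParams(
    C10=23.0097,
    k1=127.0692,
    k2=4.4952,
    kappa=0.3201,
    theta_deg=0.0008,
    D=1e-6,
)

#: Adventitial layer of the human descending thoracic aorta.
ADVENTITIA = MaterialParams(
    C10=8.2649,
    k1=71.2311,
    k2=1.6901,
    kappa=0.3013,
    theta_deg=0.001,
    D=1e-6,
)

# Inter-lamellar cohesive constants of the media: initiation traction T_C
# (kPa), critical fracture energy G_C (mN/mm) and initial stiffness K
# (mN/mm^3) for the opening mode and the two sliding modes.
MODE_I = {"TC": 131.0, "GC": 49.0, "K": 1638.0}
MODE_II = {"TC": 97.0, "GC": 200.0, "K": 35000.0}
MODE_III = {"TC": 120.0, "GC": 240.0, "K": 35000.0}


def default_cohesive_params():
    """Calibrated mixed-mode cohesive parameter set of the aortic media."""
    from .cohesive import CohesiveParams

    return CohesiveParams(
        TnC=MODE_I["TC"],
        TsC=MODE_II["TC"],
        TtC=MODE_III["TC"],
        GIC=MODE_I["GC"],
        GIIC=MODE_II["GC"],
        GIIIC=MODE_III["GC"],
        Kn=MODE_I["K"],
        Ks=MODE_II["K"],
        Kt=MODE_III["K"],
        alpha=1.0,
    )
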