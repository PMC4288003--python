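"""Domain parameter containers for the whole-body PBPK model.

Three immutable specs describe a simulation: the physiology (tissue volumes
and blood flows of a reference human), the compound (binding, clearances,
absorption and partitioning), and the dose regimen.  All specs validate
their physical invariants at construction time.

Internal unit conventions: amounts in ng, volumes in L, flows and
clearances in L/h, time in h.  External concentrations are ng/mL.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "TISSUES",
    "PERFUSION_TISSUES",
    "PERMEABILITY_TISSUES",
    "PhysiologySpec",
    "CompoundSpec",
    "DoseRegimen",
    "default_human_physiology",
    "ConfigurationError",
]

#: All anatomical tissue compartments of the whole-body structure.
TISSUES = (
    "lung",
    "adipose",
    "muscle",
    "gut",
    "spleen",
    "kidney",
    "liver",
    "rest_of_body",
)

#: Perfusion-limited tissues: a single well-stirred space with a
#: tissue:plasma partition coefficient Kp.
PERFUSION_TISSUES = ("lung", "gut", "spleen", "kidney", "rest_of_body")

#: Permeability-limited tissues: an extracellular (vascular) and an
#: intracellular space linked by a passive diffusion clearance.  The liver
#: additionally carries active uptake, biliary excretion and the serial
#: sub-unit structure.
PERMEABILITY_TISSUES = ("liver", "muscle", "adipose")

#: Fraction of liver volume occupied by bile ducts.
BILE_VOLUME_FRACTION = 0.00318

#: Physiological bile flow, 350 mL/day expressed in L/h.
DEFAULT_BILE_FLOW_L_PER_H = 0.350 / 24.0


class ConfigurationError(ValueError):
    """A spec or configuration file violates a model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class PhysiologySpec:
    """Reference-human physiology: volumes (L) and blood flows (L/h).

    ``tissue_blood_flows["liver"]`` is the hepatic *arterial* flow; total
    liver blood flow is arterial + portal (gut + spleen).  ``lung`` flow is
    cardiac output and must equal the sum of all systemic tissue flows.

    The bile-duct volume is fixed at 0.318% of liver volume; bile flow
    defaults to 350 mL/day.
    """

    body_weight: float = 70.0
    tissue_volumes: Mapping[str, float] = field(default_factory=dict)
    tissue_blood_flows: Mapping[str, float] = field(default_factory=dict)
    volume_venous_blood: float = 3.4
    volume_arterial_blood: float = 1.7
    n_liver_subunits: int = 5
    liver_blood_fraction: float = 0.2
    ec_fraction_muscle: float = 0.08
    ec_fraction_adipose: float = 0.05
    bile_flow: float = DEFAULT_BILE_FLOW_L_PER_H

    def __post_init__(self) -> None:
        _require(self.body_weight > 0, "body_weight must be > 0")
        missing = [t for t in TISSUES if t not in self.tissue_volumes]
        _require(not missing, f"tissue_volumes missing tissues: {missing}")
        missing = [t for t in TISSUES if t not in self.tissue_blood_flows]
        _require(not missing, f"tissue_blood_flows missing tissues: {missing}")
        for t, v in self.tissue_volumes.items():
            _require(t in TISSUES, f"unknown tissue in volumes: {t!r}")
            _require(v > 0, f"tissue volume for {t!r} must be > 0")
        for t, q in self.tissue_blood_flows.items():
            _require(t in TISSUES, f"unknown tissue in flows: {t!r}")
            _require(q >= 0, f"tissue blood flow for {t!r} must be >= 0")
        _require(self.volume_venous_blood > 0, "venous blood volume must be > 0")
        _require(self.volume_arterial_blood > 0, "arterial blood volume must be > 0")
        _require(self.n_liver_subunits >= 1, "n_liver_subunits must be >= 1")
        _require(0 < self.liver_blood_fraction < 1, "liver_blood_fraction in (0,1)")
        _require(0 < self.ec_fraction_muscle < 1, "ec_fraction_muscle in (0,1)")
        _require(0 < self.ec_fraction_adipose < 1, "ec_fraction_adipose in (0,1)")
        _require(self.bile_flow > 0, "bile_flow must be > 0")
        q_sys = sum(
            self.tissue_blood_flows[t] for t in TISSUES if t != "lung"
        )
        q_lung = self.tissue_blood_flows["lung"]
        _require(
            abs(q_sys - q_lung) <= 1e-6 * max(q_lung, 1.0),
            f"sum of systemic tissue flows ({q_sys:g} L/h) must equal "
            f"cardiac (lung) flow ({q_lung:g} L/h)",
        )

    @property
    def V_bile(self) -> float:
        """Bile-duct volume (L), 0.318% of liver volume."""
        return BILE_VOLUME_FRACTION * self.tissue_volumes["liver"]

    @property
    def Q_liver_bile(self) -> float:
        """Bile flow out of the liver (L/h)."""
        return self.bile_flow

    @property
    def Q_liver_total(self) -> float:
        """Total liver blood flow: hepatic artery + portal (gut + spleen)."""
        q = self.tissue_blood_flows
        return q["liver"] + q["gut"] + q["spleen"]

    def replace(self, **changes) -> "PhysiologySpec":
        return replace(self, **changes)


def default_human_physiology(n_liver_subunits: int = 5) -> PhysiologySpec:
    """A documented 70-kg reference human.

    Volumes and flows are standard reference-man magnitudes (cardiac
    output 390 L/h; liver blood flow ~87 L/h of which ~73% portal); they
    are implementation fixtures for simulation and testing.
    """
    volumes = {
        "lung": 0.53,
        "adipose": 14.0,
        "muscle": 29.0,
        "gut": 1.2,
        "spleen": 0.18,
        "kidney": 0.31,
        "liver": 1.80,
        "rest_of_body": 10.0,
    }
    flows = {
        "adipose": 19.5,
        "muscle": 66.0,
        "gut": 52.0,
        "spleen": 11.7,
        "kidney": 72.0,
        "liver": 23.4,  # hepatic artery
        "rest_of_body": 145.4,
    }
    flows["lung"] = sum(flows.values())  # cardiac output
    return PhysiologySpec(
        body_weight=70.0,
        tissue_volumes=volumes,
        tissue_blood_flows=flows,
        n_liver_subunits=n_liver_subunits,
    )


@dataclass(frozen=True)
class CompoundSpec:
    """Compound-specific parameters.

    Clearance referencing conventions:

    * ``CL_renal`` acts on venous *plasma* concentration.
    * ``CL_act_tot`` (total hepatic active uptake) and ``CL_pass_liver``
      act on *unbound plasma* concentration in liver blood
      (``fu_p * C_blood / RB_P``); the efflux leg of the passive clearance
      and ``CL_bile`` act on unbound intracellular liver concentration
      (``fu_liver * C_IC``).
    * Passive clearances in muscle and adipose are fixed ratios of the
      liver passive clearance.

    ``Kp`` maps perfusion-limited tissues to tissue:plasma partition
    coefficients; for muscle and adipose the entry is the
    intracellular:plasma ratio at passive equilibrium.
    """

    fu_p: float
    RB_P: float
    fu_liver: float
    CL_renal: float
    CL_act_tot: float
    CL_bile: float
    CL_pass_liver: float
    ka: float
    FaFg: float
    Kp: Mapping[str, float] = field(default_factory=dict)
    pass_ratio_muscle: float = 0.2
    pass_ratio_adipose: float = 0.05
    name: str = ""

    _KP_TISSUES = ("lung", "gut", "spleen", "kidney", "rest_of_body",
                   "muscle", "adipose")

    def __post_init__(self) -> None:
        _require(0 < self.fu_p <= 1, "fu_p must be in (0, 1]")
        _require(self.RB_P > 0, "RB_P must be > 0")
        _require(0 < self.fu_liver <= 1, "fu_liver must be in (0, 1]")
        for nm in ("CL_renal", "CL_act_tot", "CL_bile", "CL_pass_liver"):
            _require(getattr(self, nm) >= 0, f"{nm} must be >= 0")
        _require(self.ka > 0, "ka must be > 0")
        _require(0 < self.FaFg <= 1, "FaFg must be in (0, 1]")
        _require(self.pass_ratio_muscle >= 0, "pass_ratio_muscle must be >= 0")
        _require(self.pass_ratio_adipose >= 0, "pass_ratio_adipose must be >= 0")
        for t, kp in self.Kp.items():
            if t not in self._KP_TISSUES:
                raise ConfigurationError(
                    f"unknown tissue in Kp map: {t!r}; expected one of "
                    f"{self._KP_TISSUES}"
                )
            _require(kp > 0, f"Kp[{t!r}] must be > 0")
        missing = [t for t in self._KP_TISSUES if t not in self.Kp]
        _require(not missing, f"Kp map missing tissues: {missing}")

    def replace(self, **changes) -> "CompoundSpec":
        """Clone with fields replaced (used heavily by fitting/sensitivity)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["Kp"] = dict(self.Kp)
        return d


@dataclass(frozen=True)
class DoseRegimen:
    """A single dosing event: IV infusion over a finite duration, or oral."""

    route: str
    dose_mg: float
    infusion_duration: float | None = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        _require(self.route in ("iv_infusion", "oral"),
                 f"route must be 'iv_infusion' or 'oral', got {self.route!r}")
        _require(self.dose_mg >= 0, "dose must be >= 0")
        _require(self.start_time >= 0, "start_time must be >= 0")
        if self.route == "iv_infusion":
            _require(self.infusion_duration is not None
                     and self.infusion_duration > 0,
                     "infusion_duration must be > 0 for iv_infusion")

    @property
    def dose_ng(self) -> float:
        return self.dose_mg * 1.0e6

    @property
    def end_time(self) -> float:
        if self.route == "iv_infusion":
            return self.start_time + float(self.infusion_duration)
        return self.start_time
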