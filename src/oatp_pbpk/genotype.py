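"""Translation of in vitro OATP1B1 variant data into genotype-specific
hepatic active uptake clearances.

The gene *SLCO1B1* encodes the hepatic uptake transporter OATP1B1.  Two
common SNPs (c.388A>G, c.521T>C) define the haplotypes *1a (reference),
*1b (increased expression), and *5/*15 (reduced intrinsic activity); *5
is merged into *15 and diplotypes are restricted to homozygotes.

The algebra: the total hepatic active uptake clearance fitted on
nongenotyped (population-mean) data splits into an OATP1B1-mediated part
and an "other transporters" part by the fractional contribution
``f_OATP1B1``.  The OATP1B1 part is interpreted as the haplotype-
frequency-weighted mean of per-variant clearances, where each variant's
clearance is the reference (*1a) clearance scaled by an effective ratio
r_v = (intrinsic activity ratio) x (protein expression multiplier):

    CL_*1a = CL_OATP1B1_mean / sum_v P_v * r_v,     CL_v = r_v * CL_*1a

so the population mean is reproduced exactly.  Per-variant totals add
back the genotype-independent CL_act,other.  An ethnic scalar (e.g.
0.584 for Japanese relative to Caucasians) multiplies every active
uptake clearance, OATP1B1 and other alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .model import PBPKModel, SimulationResult
from .specs import CompoundSpec, DoseRegimen, PhysiologySpec

__all__ = [
    "VARIANTS",
    "GenotypeSpec",
    "VariantClearanceSet",
    "split_uptake",
    "oatp1b1_fraction_from_pathways",
    "variant_clearances",
    "genotyped_total",
    "apply_ethnic_scaling",
    "predict_genotype_profiles",
    "snp521_to_haplotype",
]

VARIANTS = ("star1a", "star1b", "star15")


@dataclass(frozen=True)
class GenotypeSpec:
    """Population haplotype frequencies and in vitro variant parameters.

    ``activity_ratio_*`` is the intrinsic per-transporter uptake activity
    relative to *1a; ``expression_mult_*`` the protein expression level
    relative to *1a.  ``f_OATP1B1`` is the fraction of total hepatic
    active uptake mediated by OATP1B1; ``ethnic_scalar`` multiplies all
    active uptake relative to the reference population.
    """

    frequencies: Mapping[str, float]
    activity_ratio_1b: float
    activity_ratio_15: float
    expression_mult_1b: float = 1.0
    expression_mult_15: float = 1.0
    f_OATP1B1: float = 1.0
    ethnic_scalar: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        missing = [v for v in VARIANTS if v not in self.frequencies]
        if missing:
            raise ValueError(f"frequencies missing haplotypes: {missing}")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies must sum to 1, got {total!r}")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("haplotype frequencies must be >= 0")
        for nm in ("activity_ratio_1b", "activity_ratio_15",
                   "expression_mult_1b", "expression_mult_15", "ethnic_scalar"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if not 0.0 <= self.f_OATP1B1 <= 1.0:
            raise ValueError("f_OATP1B1 must be in [0, 1]")

    def effective_ratios(self) -> dict[str, float]:
        """r_v = intrinsic activity ratio x expression multiplier; r_*1a = 1."""
        return {
            "star1a": 1.0,
            "star1b": self.activity_ratio_1b * self.expression_mult_1b,
            "star15": self.activity_ratio_15 * self.expression_mult_15,
        }

    def replace(self, **changes) -> "GenotypeSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class VariantClearanceSet:
    """Per-variant OATP1B1 clearances plus the shared non-OATP1B1 part."""

    CL_act_OATP1B1_mean: float
    CL_act_other: float
    CL_act_OATP1B1: Mapping[str, float]
    frequencies: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.CL_act_OATP1B1_mean < 0 or self.CL_act_other < 0:
            raise ValueError("clearances must be >= 0")
        if any(v < 0 for v in self.CL_act_OATP1B1.values()):
            raise ValueError("per-variant clearances must be >= 0")

    @property
    def CL_act_tot(self) -> dict[str, float]:
        """Per-variant total active uptake: OATP1B1 part + shared other."""
        return {v: cl + self.CL_act_other
                for v, cl in self.CL_act_OATP1B1.items()}


def split_uptake(CL_act_tot: float, f_OATP1B1: float) -> tuple[float, float]:
    """Split total active uptake into (OATP1B1, other) parts.

    Returns ``(f * CL, (1 - f) * CL)``; the sum equals the input exactly.
    """
    if not 0.0 <= f_OATP1B1 <= 1.0:
        raise ValueError(f"f_OATP1B1 must be in [0, 1], got {f_OATP1B1}")
    if CL_act_tot < 0:
        raise ValueError("CL_act_tot must be >= 0")
    cl_oatp = f_OATP1B1 * CL_act_tot
    return cl_oatp, CL_act_tot - cl_oatp


def oatp1b1_fraction_from_pathways(f_NTCP: float,
                                   f_OATP1B1_given_nonNTCP: float) -> float:
    """OATP1B1 fraction of total uptake from pathway bookkeeping.

    With a fraction ``f_NTCP`` of uptake due to NTCP and a fraction
    ``f_OATP1B1_given_nonNTCP`` of the remainder due to OATP1B1, the
    OATP1B1 share of the total is ``(1 - f_NTCP) * f_OATP1B1_given_nonNTCP``
    (e.g. 0.35 and 0.77 give 0.5005, i.e. ~50% for rosuvastatin).
    """
    for nm, v in (("f_NTCP", f_NTCP),
                  ("f_OATP1B1_given_nonNTCP", f_OATP1B1_given_nonNTCP)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{nm} must be in [0, 1], got {v}")
    return (1.0 - f_NTCP) * f_OATP1B1_given_nonNTCP


def variant_clearances(CL_act_OATP1B1_mean: float,
                       spec: GenotypeSpec,
                       CL_act_other: float = 0.0) -> VariantClearanceSet:
    """Per-variant OATP1B1 clearances whose frequency-weighted mean
    reproduces the nongenotyped (population-mean) clearance exactly."""
    if CL_act_OATP1B1_mean < 0:
        raise ValueError("mean clearance must be >= 0")
    ratios = spec.effective_ratios()
    weight = sum(spec.frequencies[v] * ratios[v] for v in VARIANTS)
    if weight <= 0:
        raise ValueError(
            "degenerate population: sum of frequency-weighted effective "
            "ratios is zero"
        )
    cl_1a = CL_act_OATP1B1_mean / weight
    per_variant = {v: ratios[v] * cl_1a for v in VARIANTS}
    return VariantClearanceSet(
        CL_act_OATP1B1_mean=CL_act_OATP1B1_mean,
        CL_act_other=CL_act_other,
        CL_act_OATP1B1=per_variant,
        frequencies=dict(spec.frequencies),
    )


def genotyped_total(variant_set: VariantClearanceSet) -> dict[str, float]:
    """Per-variant total active uptake clearance (OATP1B1 + other)."""
    return variant_set.CL_act_tot


def apply_ethnic_scaling(variant_set: VariantClearanceSet,
                         scalar: float) -> VariantClearanceSet:
    """Scale every active-uptake entry (per-variant OATP1B1 and the shared
    non-OATP1B1 clearance) by a population activity ratio, e.g. 0.584 for
    Japanese relative to Caucasian subjects."""
    if scalar <= 0:
        raise ValueError(f"ethnic scalar must be > 0, got {scalar}")
    return VariantClearanceSet(
        CL_act_OATP1B1_mean=scalar * variant_set.CL_act_OATP1B1_mean,
        CL_act_other=scalar * variant_set.CL_act_other,
        CL_act_OATP1B1={v: scalar * cl
                        for v, cl in variant_set.CL_act_OATP1B1.items()},
        frequencies=dict(variant_set.frequencies),
    )


def genotype_clearance_totals(compound: CompoundSpec,
                              spec: GenotypeSpec) -> dict[str, float]:
    """Per-variant CL_act_tot from a nongenotyped compound + genotype spec,
    including the ethnic scaling carried by the spec."""
    cl_oatp, cl_other = split_uptake(compound.CL_act_tot, spec.f_OATP1B1)
    vset = variant_clearances(cl_oatp, spec, CL_act_other=cl_other)
    if spec.ethnic_scalar != 1.0:
        vset = apply_ethnic_scaling(vset, spec.ethnic_scalar)
    return genotyped_total(vset)


def predict_genotype_profiles(
    compound: CompoundSpec,
    physiology: PhysiologySpec,
    spec: GenotypeSpec,
    regimen: DoseRegimen,
    time_grid: np.ndarray,
    method: str = "lsoda",
) -> dict[str, SimulationResult]:
    """Simulate each haplotype group: only CL_act_tot differs between
    variants; every other model parameter is the nongenotyped one."""
    totals = genotype_clearance_totals(compound, spec)
    out = {}
    for v in VARIANTS:
        variant_compound = compound.replace(CL_act_tot=totals[v])
        out[v] = PBPKModel(variant_compound, physiology).simulate(
            regimen, time_grid, method=method
        )
    return out


def snp521_to_haplotype(genotype: str) -> str:
    """Map a c.521T>C genotype label to the haplotype group used here.

    In studies without c.388A>G information, c.521TT is attributed to *1a
    and c.521CC to *5/*15 (merged into *15).  Heterozygotes are not
    modeled.
    """
    mapping = {"TT": "star1a", "CC": "star15",
               "c.521TT": "star1a", "c.521CC": "star15"}
    key = genotype.strip()
    if key not in mapping:
        raise ValueError(
            f"unmapped c.521 genotype {genotype!r}; known: TT, CC "
            "(heterozygotes are not modeled)"
        )
    return mapping[key]
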