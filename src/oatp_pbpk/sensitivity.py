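"""Local sensitivity analyses.

Two analyses are provided:

1. In vivo model sensitivity: each compound-specific parameter is raised
   by 1% and the normalized sensitivity coefficient
   ``S(t) = [(y'(t) - y(t)) / y(t)] / 0.01`` is computed for plasma or
   intracellular-liver concentration over the time course, or as a
   scalar for the plasma AUC over a window.  Coefficients with
   |S| >= 0.3 are flagged as influential.

2. In vitro ratio sensitivity of the genotype clearance algebra: the
   intrinsic uptake activity ratio (*1a:*1b or *1a:*15) is raised by 1%
   with the expression multiplier held fixed, and the per-variant total
   active uptake clearance is re-evaluated over a grid of fractional
   OATP1B1 contributions (0.2 to 1), holding the haplotype frequencies
   and the nongenotyped total clearance fixed.  Because the algebra is
   homogeneous in the total clearance, these coefficients are
   dimensionless and independent of its value.  |S| >= 0.1 is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import (
    VARIANTS,
    GenotypeSpec,
    predict_genotype_profiles,
    split_uptake,
    variant_clearances,
)
from .model import PBPKModel, pk_metrics
from .specs import CompoundSpec, DoseRegimen, PhysiologySpec

__all__ = [
    "SensitivityResult",
    "PERTURBABLE_PARAMETERS",
    "local_sensitivity",
    "invitro_ratio_sensitivity",
    "ratio_scenario_profiles",
]

#: Compound parameters accepted by :func:`local_sensitivity`; Kp entries
#: are addressed as ``Kp_<tissue>``.
PERTURBABLE_PARAMETERS = (
    "fu_p", "RB_P", "fu_liver", "CL_renal", "CL_act_tot", "CL_bile",
    "CL_pass_liver", "ka", "FaFg",
)

FLAG_THRESHOLD_MODEL = 0.3
FLAG_THRESHOLD_CLEARANCE = 0.1


@dataclass
class SensitivityResult:
    """Normalized sensitivity coefficients for one parameter/output pair."""

    parameter: str
    output: str
    coefficients: np.ndarray | float
    perturbation: float
    times: np.ndarray | None = None
    threshold: float = FLAG_THRESHOLD_MODEL
    flags: np.ndarray | bool = field(default=False)

    def __post_init__(self) -> None:
        if self.perturbation <= 0:
            raise ValueError("perturbation must be > 0")
        coeff = self.coefficients
        if np.isscalar(coeff):
            self.flags = bool(abs(coeff) >= self.threshold)
        else:
            with np.errstate(invalid="ignore"):
                self.flags = np.abs(coeff) >= self.threshold

    @property
    def max_abs(self) -> float:
        coeff = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        finite = coeff[np.isfinite(coeff)]
        return float(np.max(np.abs(finite))) if finite.size else np.nan

    def to_frame(self) -> pd.DataFrame:
        if self.times is None:
            return pd.DataFrame({
                "parameter": [self.parameter], "output": [self.output],
                "coefficient": [self.coefficients], "flagged": [self.flags],
            })
        return pd.DataFrame({
            "parameter": self.parameter, "output": self.output,
            "time_h": self.times, "coefficient": self.coefficients,
            "flagged": self.flags,
        })


def _perturbed_compound(compound: CompoundSpec, name: str,
                        factor: float) -> CompoundSpec:
    if name.startswith("Kp_"):
        tissue = name[3:]
        if tissue not in compound.Kp:
            raise ValueError(f"unknown Kp tissue {tissue!r}")
        kp = dict(compound.Kp)
        kp[tissue] = kp[tissue] * factor
        return compound.replace(Kp=kp)
    if name not in PERTURBABLE_PARAMETERS:
        raise ValueError(
            f"unknown parameter {name!r}; perturbable: "
            f"{PERTURBABLE_PARAMETERS} or Kp_<tissue>")
    value = getattr(compound, name)
    if value == 0:
        raise ValueError(
            f"parameter {name!r} is zero; a relative perturbation is "
            "undefined — perturb in absolute-step mode instead")
    return compound.replace(**{name: value * factor})


def local_sensitivity(
    compound: CompoundSpec,
    physiology: PhysiologySpec,
    regimen: DoseRegimen,
    parameter_name: str,
    output: str = "plasma_conc",
    window: tuple[float, float] = (0.0, 8.0),
    perturbation: float = 0.01,
    grid_spacing: float = 0.1,
    scheme: str = "forward",
    method: str = "expm",
) -> SensitivityResult:
    """Normalized local sensitivity of a model output to one parameter.

    ``output`` is ``plasma_conc`` or ``liver_conc`` (time-resolved over
    the window) or ``AUC_plasma`` (scalar).  ``scheme="central"``
    computes the second-order central difference, used as the
    convergence oracle for the default forward scheme.
    """
    if output not in ("plasma_conc", "liver_conc", "AUC_plasma"):
        raise ValueError(f"unknown output {output!r}")
    t0, t1 = window
    grid = np.arange(t0, t1 + grid_spacing / 2, grid_spacing)
    grid[0] = t0

    def run(factor: float) -> np.ndarray:
        c = (_perturbed_compound(compound, parameter_name, factor)
             if factor != 1.0 else compound)
        res = PBPKModel(c, physiology).simulate(regimen, grid, method=method)
        if output == "AUC_plasma":
            return np.array([pk_metrics(res, t0, t1)["AUC"]])
        return res.plasma_conc if output == "plasma_conc" else res.liver_conc

    y0 = run(1.0)
    h = perturbation
    with np.errstate(divide="ignore", invalid="ignore"):
        if scheme == "forward":
            dy = run(1.0 + h) - y0
            coeff = np.where(y0 > 0, dy / y0 / h, np.nan)
        elif scheme == "central":
            dy = run(1.0 + h) - run(1.0 - h)
            coeff = np.where(y0 > 0, dy / y0 / (2 * h), np.nan)
        else:
            raise ValueError("scheme must be 'forward' or 'central'")
    if output == "AUC_plasma":
        return SensitivityResult(
            parameter=parameter_name, output=output,
            coefficients=float(coeff[0]), perturbation=h,
            threshold=FLAG_THRESHOLD_MODEL)
    return SensitivityResult(
        parameter=parameter_name, output=output, coefficients=coeff,
        perturbation=h, times=grid, threshold=FLAG_THRESHOLD_MODEL)


def _variant_totals(spec: GenotypeSpec, f: float) -> dict[str, float]:
    """Per-variant CL_act_tot for unit nongenotyped clearance."""
    cl_oatp, cl_other = split_uptake(1.0, f)
    vset = variant_clearances(cl_oatp, spec, CL_act_other=cl_other)
    return vset.CL_act_tot


def invitro_ratio_sensitivity(
    spec: GenotypeSpec,
    f_grid: np.ndarray,
    target_ratio: str = "ratio_15",
    perturbation: float = 0.01,
) -> pd.DataFrame:
    """Sensitivity of per-variant CL_act_tot to an intrinsic activity
    ratio, across fractional OATP1B1 contributions.

    Returns a tidy table with columns ``f_OATP1B1``, ``variant``,
    ``coefficient`` and ``flagged`` (|S| >= 0.1).  The expression
    multiplier is held fixed; only the intrinsic ratio is perturbed.
    """
    f_grid = np.atleast_1d(np.asarray(f_grid, dtype=float))
    if f_grid.size == 0:
        raise ValueError("f_grid must not be empty")
    if np.any((f_grid < 0) | (f_grid > 1)):
        raise ValueError("f_grid values must lie in [0, 1]")
    if target_ratio not in ("ratio_1b", "ratio_15"):
        raise ValueError("target_ratio must be 'ratio_1b' or 'ratio_15'")
    attr = ("activity_ratio_1b" if target_ratio == "ratio_1b"
            else "activity_ratio_15")
    perturbed_spec = spec.replace(
        **{attr: getattr(spec, attr) * (1.0 + perturbation)})

    rows = []
    for f in f_grid:
        base = _variant_totals(spec, f)
        new = _variant_totals(perturbed_spec, f)
        for v in VARIANTS:
            coeff = (new[v] - base[v]) / base[v] / perturbation
            rows.append({
                "f_OATP1B1": f, "variant": v, "coefficient": coeff,
                "flagged": abs(coeff) >= FLAG_THRESHOLD_CLEARANCE,
            })
    return pd.DataFrame(rows)


def ratio_scenario_profiles(
    compound: CompoundSpec,
    physiology: PhysiologySpec,
    spec: GenotypeSpec,
    regimen: DoseRegimen,
    ratio_15_values,
    time_grid: np.ndarray | None = None,
    method: str = "expm",
) -> dict[float, dict]:
    """Per-variant profiles for each candidate *1a:*15 intrinsic activity
    ratio (e.g. the two literature values 0.20 and 0.50), regenerating
    the genotype clearances at each ratio."""
    ratios = list(np.atleast_1d(np.asarray(ratio_15_values, dtype=float)))
    if any(r <= 0 for r in ratios):
        raise ValueError("ratio values must be > 0")
    if time_grid is None:
        time_grid = np.arange(0.0, 24.01, 0.1)
    out = {}
    for r in ratios:
        scenario = spec.replace(activity_ratio_15=r)
        out[r] = predict_genotype_profiles(
            compound, physiology, scenario, regimen, time_grid,
            method=method)
    return out
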