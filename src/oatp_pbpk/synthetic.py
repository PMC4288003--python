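"""Synthetic study generator: fixture compounds, noisy mean plasma
profiles, and genotype-stratified cohorts.

Fixture compound clearance/absorption magnitudes are package fixtures
chosen to give a pravastatin-like oral profile (tmax ~ 1 h, mixed renal +
hepatic elimination) and a rosuvastatin-like profile (slow absorption,
tmax ~ 4 h, uptake-dominated); the genotype constants (fractional
OATP1B1 contributions, in vitro activity ratios, expression multipliers,
haplotype frequencies) are the published in vitro values.

Observation noise is multiplicative lognormal: a replicate concentration
is the model value times exp(e), e ~ N(0, sigma^2) with
sigma = sqrt(ln(1 + cv^2)), so log-residuals have mean ~0 and SD ~cv.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import GenotypeSpec, oatp1b1_fraction_from_pathways, \
    predict_genotype_profiles
from .model import PBPKModel
from .specs import CompoundSpec, DoseRegimen, PhysiologySpec, \
    default_human_physiology

__all__ = [
    "ConcentrationTimeSeries",
    "NoiseModel",
    "FIXTURE_NAMES",
    "make_fixture",
    "generate_dataset",
    "generate_genotyped_cohort",
]

FIXTURE_NAMES = ("pravastatin_like", "rosuvastatin_like", "fluvastatin_like")

#: European haplotype frequencies: *1a 56%, *1b 26%, *5/*15 18%.
EUROPEAN_FREQUENCIES = {"star1a": 0.56, "star1b": 0.26, "star15": 0.18}

#: Intrinsic OATP1B1 activity ratio, Japanese relative to Caucasians.
JAPANESE_ETHNIC_SCALAR = 0.584


@dataclass
class ConcentrationTimeSeries:
    """An observed or synthetic mean plasma profile with dosing metadata."""

    times: np.ndarray
    concentrations: np.ndarray
    regimen: DoseRegimen
    sd: np.ndarray | None = None
    label: str = ""
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.concentrations.shape != self.times.shape:
            raise ValueError("concentrations must match times in shape")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self):
        import pandas as pd

        d = {"time_h": self.times, "conc_ng_per_mL": self.concentrations}
        if self.sd is not None:
            d["sd_ng_per_mL"] = self.sd
        return pd.DataFrame(d)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal observation noise with coefficient of
    variation ``cv``; ``cv = 0`` means noise-free."""

    cv: float = 0.2
    seed: int = 0
    kind: str = "lognormal_cv"

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.kind != "lognormal_cv":
            raise ValueError(f"unknown noise kind {self.kind!r}")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv ** 2)))


def _pravastatin_like() -> tuple[CompoundSpec, GenotypeSpec, dict]:
    compound = CompoundSpec(
        name="pravastatin_like",
        fu_p=0.57, RB_P=0.56, fu_liver=0.39,
        CL_renal=24.0, CL_act_tot=90.0, CL_bile=18.0, CL_pass_liver=8.0,
        ka=0.7, FaFg=0.46,
        Kp={"lung": 0.45, "gut": 1.0, "spleen": 0.45, "kidney": 1.6,
            "rest_of_body": 0.8, "muscle": 1.2, "adipose": 0.3},
    )
    genotype = GenotypeSpec(
        name="pravastatin-caucasian",
        frequencies=EUROPEAN_FREQUENCIES,
        activity_ratio_1b=0.81, activity_ratio_15=0.35,
        expression_mult_1b=2.0, expression_mult_15=1.0,
        f_OATP1B1=0.83,
    )
    regimens = {
        "iv": DoseRegimen("iv_infusion", 9.9, infusion_duration=0.5),
        "oral": DoseRegimen("oral", 19.2),
        "oral_genotyped": DoseRegimen("oral", 40.0),
    }
    return compound, genotype, regimens


def _rosuvastatin_like() -> tuple[CompoundSpec, GenotypeSpec, dict]:
    compound = CompoundSpec(
        name="rosuvastatin_like",
        fu_p=0.12, RB_P=0.69, fu_liver=0.06,
        CL_renal=10.0, CL_act_tot=120.0, CL_bile=35.0, CL_pass_liver=15.0,
        ka=0.12, FaFg=0.50,
        Kp={"lung": 0.5, "gut": 2.0, "spleen": 0.5, "kidney": 3.0,
            "rest_of_body": 2.0, "muscle": 4.0, "adipose": 1.0},
    )
    genotype = GenotypeSpec(
        name="rosuvastatin-caucasian",
        frequencies=EUROPEAN_FREQUENCIES,
        activity_ratio_1b=0.82, activity_ratio_15=0.15,
        expression_mult_1b=2.0, expression_mult_15=1.0,
        # 35% NTCP; 77% of the non-NTCP remainder is OATP1B1 -> 0.5005
        f_OATP1B1=oatp1b1_fraction_from_pathways(0.35, 0.77),
    )
    regimens = {
        "iv": DoseRegimen("iv_infusion", 8.0, infusion_duration=0.5),
        "oral": DoseRegimen("oral", 40.0),
        "oral_genotyped": DoseRegimen("oral", 10.0),
    }
    return compound, genotype, regimens


def _fluvastatin_like() -> tuple[CompoundSpec, GenotypeSpec, dict]:
    # in vitro: c.521T>C does not impair OATP1B1 uptake of fluvastatin,
    # so the *15 intrinsic ratio and expression multiplier are both 1.
    compound = CompoundSpec(
        name="fluvastatin_like",
        fu_p=0.01, RB_P=0.6, fu_liver=0.02,
        CL_renal=0.5, CL_act_tot=3000.0, CL_bile=10.0, CL_pass_liver=150.0,
        ka=1.5, FaFg=0.9,
        Kp={"lung": 0.6, "gut": 1.5, "spleen": 0.6, "kidney": 1.2,
            "rest_of_body": 0.6, "muscle": 1.0, "adipose": 0.8},
    )
    genotype = GenotypeSpec(
        name="fluvastatin-caucasian",
        frequencies=EUROPEAN_FREQUENCIES,
        activity_ratio_1b=1.0, activity_ratio_15=1.0,
        expression_mult_1b=1.0, expression_mult_15=1.0,
        f_OATP1B1=0.6,
    )
    regimens = {
        "iv": DoseRegimen("iv_infusion", 2.0, infusion_duration=0.5),
        "oral": DoseRegimen("oral", 40.0),
        "oral_genotyped": DoseRegimen("oral", 40.0),
    }
    return compound, genotype, regimens


def make_fixture(name: str) -> tuple[CompoundSpec, GenotypeSpec, dict]:
    """Return (CompoundSpec, GenotypeSpec, default DoseRegimens) for a
    named fixture compound.

    Regimens: ``iv`` and ``oral`` are the nongenotyped study doses;
    ``oral_genotyped`` is the genotyped-cohort oral dose.
    """
    builders = {
        "pravastatin_like": _pravastatin_like,
        "rosuvastatin_like": _rosuvastatin_like,
        "fluvastatin_like": _fluvastatin_like,
    }
    if name not in builders:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(builders)}"
        )
    return builders[name]()


def generate_dataset(
    compound: CompoundSpec,
    physiology: PhysiologySpec,
    regimen: DoseRegimen,
    sampling_times: np.ndarray,
    noise: NoiseModel = NoiseModel(cv=0.0),
    n_replicates: int = 12,
    label: str = "",
) -> ConcentrationTimeSeries:
    """Simulate the true profile and return the mean +/- SD of
    ``n_replicates`` lognormal-noised copies at ``sampling_times``.

    With ``cv = 0`` the output equals the model prediction exactly and
    the SD is zero.
    """
    sampling_times = np.asarray(sampling_times, dtype=float)
    grid = sampling_times
    if grid[0] > regimen.start_time:
        grid = np.concatenate([[regimen.start_time], grid])
    result = PBPKModel(compound, physiology).simulate(regimen, grid,
                                                      method="expm")
    truth = np.interp(sampling_times, result.time_grid, result.plasma_conc)
    if noise.cv == 0.0:
        conc, sd = truth, np.zeros_like(truth)
    else:
        rng = np.random.default_rng(noise.seed)
        eps = rng.normal(0.0, noise.sigma,
                         size=(n_replicates, truth.size))
        reps = truth[None, :] * np.exp(eps)
        conc = reps.mean(axis=0)
        sd = reps.std(axis=0, ddof=1)
    return ConcentrationTimeSeries(
        times=sampling_times, concentrations=conc, sd=sd,
        regimen=regimen, label=label or compound.name,
        n_subjects=n_replicates,
    )


def generate_genotyped_cohort(
    compound: CompoundSpec,
    physiology: PhysiologySpec,
    spec: GenotypeSpec,
    regimen: DoseRegimen,
    sampling_times: np.ndarray,
    noise: NoiseModel = NoiseModel(cv=0.0),
    n_per_group: int = 12,
) -> dict[str, ConcentrationTimeSeries]:
    """Genotype-stratified synthetic cohort: per-haplotype mean profiles
    generated from the genotype clearance algebra, independently noised
    per group."""
    sampling_times = np.asarray(sampling_times, dtype=float)
    grid = sampling_times
    if grid[0] > regimen.start_time:
        grid = np.concatenate([[regimen.start_time], grid])
    profiles = predict_genotype_profiles(compound, physiology, spec,
                                         regimen, grid, method="expm")
    out = {}
    for j, (variant, result) in enumerate(sorted(profiles.items())):
        truth = np.interp(sampling_times, result.time_grid,
                          result.plasma_conc)
        if noise.cv == 0.0:
            conc, sd = truth, np.zeros_like(truth)
        else:
            rng = np.random.default_rng(noise.seed + j)
            eps = rng.normal(0.0, noise.sigma,
                             size=(n_per_group, truth.size))
            reps = truth[None, :] * np.exp(eps)
            conc = reps.mean(axis=0)
            sd = reps.std(axis=0, ddof=1)
        out[variant] = ConcentrationTimeSeries(
            times=sampling_times, concentrations=conc, sd=sd,
            regimen=regimen, label=f"{compound.name}:{variant}",
            n_subjects=n_per_group,
        )
    return out


def default_physiology() -> PhysiologySpec:
    """Convenience re-export of the 70-kg reference human."""
    return default_human_physiology()
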