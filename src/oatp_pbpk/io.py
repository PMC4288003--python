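"""Configuration and dataset I/O.

External files use explicit unit suffixes in key names (``_L``,
``_L_per_h``, ``_mL_per_day``, ``_kg``, ``_h``) and are converted to the
package's internal units (ng, L, h) at load time.  Unknown keys are
rejected with the offending key named, so silent typos cannot change a
simulation.

Datasets are CSVs with columns ``time_h``, ``conc_ng_per_mL`` and an
optional ``sd_ng_per_mL``, paired with a sidecar YAML carrying the dose
regimen.  A :class:`RunManifest` records seeds, configs and package
version for reproducibility.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotype import GenotypeSpec
from .specs import CompoundSpec, ConfigurationError, DoseRegimen, \
    PhysiologySpec
from .synthetic import ConcentrationTimeSeries

__all__ = [
    "load_physiology", "load_compound", "load_genotype", "load_regimen",
    "load_configs", "load_genotype_preset",
    "read_dataset", "write_dataset", "write_simulation",
    "RunManifest",
]

_DATA_DIR = Path(__file__).parent / "data"


def _load_yaml(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return doc


def _check_keys(doc: dict, allowed: set, required: set, path) -> None:
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown key(s) {sorted(unknown)}; allowed keys are "
            f"{sorted(allowed)}")
    missing = required - set(doc)
    if missing:
        raise ConfigurationError(
            f"{path}: missing required key(s) {sorted(missing)}")


def load_physiology(path) -> PhysiologySpec:
    doc = _load_yaml(path)
    required = {"body_weight_kg", "tissue_volumes_L",
                "tissue_blood_flows_L_per_h"}
    allowed = required | {
        "volume_venous_blood_L", "volume_arterial_blood_L",
        "n_liver_subunits", "liver_blood_fraction",
        "ec_fraction_muscle", "ec_fraction_adipose", "bile_flow_mL_per_day",
    }
    _check_keys(doc, allowed, required, path)
    kwargs = dict(
        body_weight=doc["body_weight_kg"],
        tissue_volumes=dict(doc["tissue_volumes_L"]),
        tissue_blood_flows=dict(doc["tissue_blood_flows_L_per_h"]),
    )
    passthrough = {
        "volume_venous_blood_L": "volume_venous_blood",
        "volume_arterial_blood_L": "volume_arterial_blood",
        "n_liver_subunits": "n_liver_subunits",
        "liver_blood_fraction": "liver_blood_fraction",
        "ec_fraction_muscle": "ec_fraction_muscle",
        "ec_fraction_adipose": "ec_fraction_adipose",
    }
    for key, attr in passthrough.items():
        if key in doc:
            kwargs[attr] = doc[key]
    if "bile_flow_mL_per_day" in doc:
        kwargs["bile_flow"] = doc["bile_flow_mL_per_day"] / 1000.0 / 24.0
    try:
        return PhysiologySpec(**kwargs)
    except (ConfigurationError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def load_compound(path) -> CompoundSpec:
    doc = _load_yaml(path)
    unit_keys = {
        "CL_renal_L_per_h": "CL_renal",
        "CL_act_tot_L_per_h": "CL_act_tot",
        "CL_bile_L_per_h": "CL_bile",
        "CL_pass_liver_L_per_h": "CL_pass_liver",
        "ka_per_h": "ka",
    }
    plain_keys = {"name", "fu_p", "RB_P", "fu_liver", "FaFg", "Kp",
                  "pass_ratio_muscle", "pass_ratio_adipose"}
    required = (set(unit_keys) | plain_keys) - {
        "name", "pass_ratio_muscle", "pass_ratio_adipose"}
    _check_keys(doc, set(unit_keys) | plain_keys, required, path)
    kwargs = {attr: doc[key] for key, attr in unit_keys.items()}
    for key in plain_keys:
        if key in doc:
            kwargs[key] = doc[key]
    try:
        return CompoundSpec(**kwargs)
    except (ConfigurationError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def load_genotype(path) -> GenotypeSpec:
    doc = _load_yaml(path)
    required = {"frequencies", "activity_ratio_1b", "activity_ratio_15",
                "f_OATP1B1"}
    allowed = required | {"name", "expression_mult_1b", "expression_mult_15",
                          "ethnic_scalar"}
    _check_keys(doc, allowed, required, path)
    try:
        return GenotypeSpec(**doc)
    except ValueError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def load_regimen(path) -> DoseRegimen:
    doc = _load_yaml(path)
    required = {"route", "dose_mg"}
    allowed = required | {"infusion_duration_h", "start_time_h"}
    _check_keys(doc, allowed, required, path)
    try:
        return DoseRegimen(
            route=doc["route"], dose_mg=doc["dose_mg"],
            infusion_duration=doc.get("infusion_duration_h"),
            start_time=doc.get("start_time_h", 0.0),
        )
    except (ConfigurationError, ValueError) as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def load_configs(compound_path, physiology_path, genotype_path=None,
                 regimen_path=None):
    """Load the full configuration tuple
    (CompoundSpec, PhysiologySpec, GenotypeSpec | None, DoseRegimen | None).
    """
    compound = load_compound(compound_path)
    physiology = load_physiology(physiology_path)
    genotype = load_genotype(genotype_path) if genotype_path else None
    regimen = load_regimen(regimen_path) if regimen_path else None
    return compound, physiology, genotype, regimen


def load_genotype_preset(name: str) -> GenotypeSpec:
    """Load a shipped genotype preset, e.g. ``pravastatin-caucasian``,
    ``rosuvastatin-caucasian`` or ``pravastatin-japanese``."""
    path = _DATA_DIR / f"genotype_{name.replace('-', '_')}.yaml"
    if not path.exists():
        available = sorted(
            p.stem.removeprefix("genotype_").replace("_", "-")
            for p in _DATA_DIR.glob("genotype_*.yaml"))
        raise ConfigurationError(
            f"unknown genotype preset {name!r}; available: {available}")
    return load_genotype(path)


def default_physiology_path() -> Path:
    return _DATA_DIR / "physiology_human_70kg.yaml"


# ----------------------------------------------------------------------
# datasets
# ----------------------------------------------------------------------
def read_dataset(csv_path, regimen_path=None,
                 regimen: DoseRegimen | None = None,
                 label: str = "") -> ConcentrationTimeSeries:
    """Read a concentration-time CSV plus its dose-regimen sidecar."""
    df = pd.read_csv(csv_path)
    for col in ("time_h", "conc_ng_per_mL"):
        if col not in df.columns:
            raise ConfigurationError(
                f"{csv_path}: missing required column {col!r}")
    bad = df.index[df["time_h"].isna() | df["conc_ng_per_mL"].isna()]
    if len(bad):
        raise ConfigurationError(
            f"{csv_path}: malformed value in row {int(bad[0]) + 2} "
            "(1-based, including header)")
    if regimen is None:
        if regimen_path is None:
            raise ConfigurationError(
                "either regimen_path or regimen must be provided")
        regimen = load_regimen(regimen_path)
    sd = df["sd_ng_per_mL"].to_numpy() if "sd_ng_per_mL" in df.columns \
        else None
    return ConcentrationTimeSeries(
        times=df["time_h"].to_numpy(),
        concentrations=df["conc_ng_per_mL"].to_numpy(),
        sd=sd, regimen=regimen, label=label or str(csv_path),
    )


def write_dataset(dataset: ConcentrationTimeSeries, csv_path,
                  regimen_path=None) -> None:
    dataset.to_frame().to_csv(csv_path, index=False)
    if regimen_path is not None:
        r = dataset.regimen
        doc = {"route": r.route, "dose_mg": r.dose_mg,
               "start_time_h": r.start_time}
        if r.infusion_duration is not None:
            doc["infusion_duration_h"] = r.infusion_duration
        with open(regimen_path, "w") as fh:
            yaml.safe_dump(doc, fh)


def write_simulation(result, csv_path, amounts_path=None) -> None:
    """Write a simulation trace (and optionally per-compartment amounts)."""
    result.to_frame().to_csv(csv_path, index=False)
    if amounts_path is not None:
        result.amounts_frame().to_csv(amounts_path, index=False)


# ----------------------------------------------------------------------
# reproducibility manifest
# ----------------------------------------------------------------------
@dataclass
class RunManifest:
    """Record of one CLI run: command, configs, seeds, version, time."""

    command: str
    config_paths: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
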