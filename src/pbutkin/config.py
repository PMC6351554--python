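"""Scenario configuration: schema, validation, presets, tabular writers.

A scenario is one declarative YAML file with six blocks — patient, solutes,
dialyzer, tube, prescription, numerics, output — validated by pydantic with
units declared in field names.  ``load_preset`` ships the baseline
high-flux HD scenario and its six modality variants (pre/post-dilution HDF,
ideal membrane adsorption, tryptophan- and ibuprofen-augmented HD).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .binding import BindingSolute, SoluteDefinition, calibrate_binding
from .circuit import DialyzerSpec, TubeSpec
from .engine import MODALITIES, NumericsConfig, Prescription
from .patient import PatientParams
from .pharmacology import IBUPROFEN, TRYPTOPHAN, DrugSpec

__all__ = [
    "ScenarioConfig",
    "load_config",
    "save_config",
    "load_preset",
    "preset_names",
    "write_outcomes",
    "write_timeseries",
]


class PatientBlock(BaseModel):
    """Anuric HD patient: volumes, hematocrit, transfer rates, albumin."""

    V_pl_L: float = Field(3.5, gt=0, description="initial plasma volume")
    V_is_L: float = Field(12.0, gt=0, description="initial interstitial volume")
    V_ic_L: float = Field(28.0, gt=0, description="intracellular distribution volume")
    hematocrit: float = Field(0.35, gt=0, lt=1)
    K_ip_mL_min: float = Field(1135.0, gt=0, description="plasma-interstitial free-solute transfer")
    K_ic_mL_min: float = Field(100.0, gt=0, description="interstitial-intracellular transfer")
    albumin_pl_uM: float = Field(600.0, ge=0, description="total plasma albumin (~4 g/dL)")
    albumin_is_uM: float = Field(300.0, ge=0, description="total interstitial albumin (50% of plasma)")

    def to_params(self) -> PatientParams:
        return PatientParams(
            V_pl0=self.V_pl_L, V_is0=self.V_is_L, V_ic=self.V_ic_L,
            hematocrit=self.hematocrit, K_ip=self.K_ip_mL_min,
            K_ic=self.K_ic_mL_min, albumin_pl=self.albumin_pl_uM * 1e-6,
            albumin_is=self.albumin_is_uM * 1e-6,
        )


class SoluteBlock(BaseModel):
    """One protein-bound toxin: initial totals, free fraction, generation."""

    name: str
    total_uM: float = Field(ge=0)
    free_fraction: float = Field(gt=0, le=1)
    mol_weight: float = Field(gt=0)
    generation_mg_min: float = Field(0.0, ge=0)

    def to_definition(self) -> SoluteDefinition:
        return SoluteDefinition(
            name=self.name, total_conc_init=self.total_uM * 1e-6,
            free_fraction_init=self.free_fraction, mol_weight=self.mol_weight,
            generation_rate=self.generation_mg_min,
        )


class DialyzerBlock(BaseModel):
    """High-flux hollow-fiber dialyzer geometry (F180NR-class defaults)."""

    n_fibers: int = Field(12300, gt=0)
    fiber_inner_radius_um: float = Field(105.0, gt=0)
    fiber_wall_um: float = Field(35.0, gt=0)
    fiber_length_m: float = Field(0.23, gt=0)
    blood_area_per_fiber_m2: float = Field(3.5e-8, gt=0)
    dialysate_area_per_fiber_m2: float = Field(4.1e-8, gt=0)
    housing_diameter_m: float = Field(0.04, gt=0)
    KoA_mL_min: float = Field(600.0, gt=0, description="small-solute membrane coefficient")
    sigma_large: float = Field(0.999, ge=0, le=1, description="albumin/complex reflection")

    def to_spec(self) -> DialyzerSpec:
        import numpy as np
        sigma = np.array([0.0, self.sigma_large] * 3 + [self.sigma_large])
        return DialyzerSpec(
            N=self.n_fibers, r_f=self.fiber_inner_radius_um * 1e-6,
            t_f=self.fiber_wall_um * 1e-6, L=self.fiber_length_m,
            A=self.blood_area_per_fiber_m2, A_d=self.dialysate_area_per_fiber_m2,
            D_h=self.housing_diameter_m, KoA=self.KoA_mL_min, sigma=sigma,
        )


class TubeBlock(BaseModel):
    """Bloodline segment between infusion site and dialyzer (and its venous mirror)."""

    length_m: float = Field(0.5, gt=0)
    area_m2: float = Field(1.81e-5, gt=0, description="4.8 mm ID adult bloodline")

    def to_spec(self) -> TubeSpec:
        return TubeSpec(length=self.length_m, area=self.area_m2)


class DrugBlock(BaseModel):
    """Displacer drug; ``preset`` resolves tryptophan/ibuprofen defaults."""

    preset: Optional[Literal["tryptophan_2000mg", "ibuprofen_800mg"]] = None
    name: Optional[str] = None
    mol_weight: Optional[float] = None
    K_A_per_M: Optional[float] = None
    dose_mg: Optional[float] = None
    carrier_volume_mL: Optional[float] = None
    infusion_duration_min: Optional[float] = None
    total_half_life_min: Optional[float] = None
    lambda_free_per_min: Optional[float] = None

    def to_spec(self) -> DrugSpec:
        if self.preset:
            base = TRYPTOPHAN if self.preset == "tryptophan_2000mg" else IBUPROFEN
            spec = base
        else:
            missing = [k for k in ("name", "mol_weight", "K_A_per_M", "dose_mg",
                                   "carrier_volume_mL", "infusion_duration_min",
                                   "total_half_life_min")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(f"drug block missing fields: {missing}")
            spec = DrugSpec(
                name=self.name, mol_weight=self.mol_weight, K_A=self.K_A_per_M,
                dose=self.dose_mg, carrier_volume=self.carrier_volume_mL,
                infusion_duration=self.infusion_duration_min,
                total_half_life=self.total_half_life_min,
            )
        if self.lambda_free_per_min is not None:
            from dataclasses import replace
            spec = replace(spec, lambda_free=self.lambda_free_per_min)
        return spec


class PrescriptionBlock(BaseModel):
    """Session prescription: modality, flows, fluid volumes, duration."""

    modality: Literal["hd", "hdf_pre", "hdf_post", "hd_adsorption", "hd_displacer"] = "hd"
    Q_b_mL_min: float = Field(300.0, gt=0)
    Q_di_mL_min: float = Field(800.0, gt=0)
    uf_volume_L: float = Field(2.4, ge=0)
    duration_min: float = Field(240.0, gt=0)
    replacement_volume_L: float = Field(0.0, ge=0)
    drug: Optional[DrugBlock] = None

    def to_prescription(self) -> Prescription:
        return Prescription(
            modality=self.modality, Q_b=self.Q_b_mL_min, Q_di=self.Q_di_mL_min,
            uf_volume=self.uf_volume_L, duration=self.duration_min,
            replacement_volume=self.replacement_volume_L,
            drug=self.drug.to_spec() if self.drug else None,
        )


class NumericsBlock(BaseModel):
    """Grid sizes and integrator tolerances; seed recorded for provenance."""

    nx: int = Field(100, ge=10)
    nt: int = Field(20, ge=4)
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-12, gt=0)
    t_eval_step_min: float = Field(2.0, gt=0)
    seed: int = 0

    def to_numerics(self) -> NumericsConfig:
        return NumericsConfig(nx=self.nx, nt=self.nt, rtol=self.rtol,
                              atol=self.atol, t_eval_step=self.t_eval_step_min)


class OutputBlock(BaseModel):
    out_dir: str = "out"


class ScheduleBlock(BaseModel):
    """Multi-session schedule: horizon and weekly session pattern."""

    n_days: int = Field(28, gt=0)
    week_pattern: list[int] = Field(default_factory=lambda: [0, 2, 4])
    intake_per_interval_L: Optional[float] = None

    @field_validator("week_pattern")
    @classmethod
    def _check_days(cls, v):
        if not v or any(d < 0 or d > 6 for d in v) or sorted(set(v)) != sorted(v):
            raise ValueError("week_pattern must be distinct weekdays in 0..6")
        return v


class ScenarioConfig(BaseModel):
    """A fully validated simulation scenario."""

    patient: PatientBlock = Field(default_factory=PatientBlock)
    solutes: list[SoluteBlock]
    dialyzer: DialyzerBlock = Field(default_factory=DialyzerBlock)
    tube: TubeBlock = Field(default_factory=TubeBlock)
    prescription: PrescriptionBlock = Field(default_factory=PrescriptionBlock)
    numerics: NumericsBlock = Field(default_factory=NumericsBlock)
    schedule: ScheduleBlock = Field(default_factory=ScheduleBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    def build_solutes(self) -> list[BindingSolute]:
        """Calibrate binding constants from the configured totals and free fractions."""
        defs = [s.to_definition() for s in self.solutes]
        return calibrate_binding(defs, self.patient.albumin_pl_uM * 1e-6)

    def build(self):
        """(params, solutes, prescription, dialyzer, tube, numerics) domain objects."""
        return (
            self.patient.to_params(), self.build_solutes(),
            self.prescription.to_prescription(), self.dialyzer.to_spec(),
            self.tube.to_spec(), self.numerics.to_numerics(),
        )


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario YAML; errors name the offending field."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(
            f"{path}: expected a mapping with blocks "
            "(patient, solutes, dialyzer, tube, prescription, numerics)"
        )
    return ScenarioConfig.model_validate(raw)


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


_PRESET_OVERRIDES: dict[str, dict] = {
    "baseline_hd": {},
    "baseline_hdf_pre20": {"modality": "hdf_pre", "replacement_volume_L": 20.0},
    "baseline_hdf_pre60": {"modality": "hdf_pre", "replacement_volume_L": 60.0},
    "baseline_hdf_post20": {"modality": "hdf_post", "replacement_volume_L": 20.0},
    "baseline_adsorption": {"modality": "hd_adsorption"},
    "baseline_tryptophan": {"modality": "hd_displacer",
                          "drug": {"preset": "tryptophan_2000mg"}},
    "baseline_ibuprofen": {"modality": "hd_displacer",
                         "drug": {"preset": "ibuprofen_800mg"}},
}


def preset_names() -> list[str]:
    return list(_PRESET_OVERRIDES)


def load_preset(name: str = "baseline_hd") -> ScenarioConfig:
    """Baseline high-flux HD scenario and its modality variants."""
    if name not in _PRESET_OVERRIDES:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    ref = importlib.resources.files("pbutkin").joinpath("presets/baseline_hd.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    overrides = _PRESET_OVERRIDES[name]
    raw.setdefault("prescription", {})
    for key, val in overrides.items():
        raw["prescription"][key] = val
    return ScenarioConfig.model_validate(raw)


def write_outcomes(table: pd.DataFrame, path: str | Path) -> None:
    """Deterministic outcome CSV (modality, toxin, RR_pct, removal_mg, clearance_mL_min)."""
    cols = [c for c in ("modality", "toxin", "RR_pct", "removal_mg",
                        "clearance_mL_min", "removal_improvement_pct")
            if c in table.columns]
    table[cols].to_csv(path, index=False, float_format="%.6g")


def write_timeseries(series: pd.DataFrame, path: str | Path) -> None:
    """Tidy time-series CSV with units in column headers."""
    series.to_csv(path, index=False, float_format="%.8g")
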