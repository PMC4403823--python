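"""Study orchestration: simulate -> process -> fit -> invivo -> circulate.

A :class:`StudyConfig` (YAML- or dict-backed, pydantic-validated) describes
the species, their ground-truth pigments, the chamber protocol, noise and
seeds; :func:`run_study` executes every stage per species and temperature
and collects a :class:`RunReport` with a Table-1-shaped binding-parameter
table, a transport-budget grid over temperatures and venous PO2 in
{4, 1} kPa, and a circulation summary.  All randomness derives from one
root seed via named substreams, so a config runs to byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import circulation as circ
from . import curves as cv
from . import synthetic as syn
from . import traces as tp
from . import transport as tx
from .errors import BluesatError, PH50Undefined

__all__ = [
    "StudyConfig",
    "SpeciesConfig",
    "RunReport",
    "run_study",
    "write_report",
    "default_study_config",
    "substream_seed",
    "validate_report_payload",
]

log = logging.getLogger(__name__)


def substream_seed(root: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the root seed."""
    digest = hashlib.sha256(f"{root}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class PigmentConfig(BaseModel):
    capacity: float = 1.58
    bohr_slope: float = -1.22
    p50_ref: float = 2.34
    ph_ref: float = 7.27
    steepness: float = 8.0
    asymmetry: float = 1.0
    lower_asymptote: float = 0.0
    temp_coeff: float = 0.0
    ref_temp: float = 10.0
    lower_asymptote_dT: float = 0.0

    def build(self) -> syn.GroundTruthPigment:
        return syn.GroundTruthPigment(**self.model_dump())


class SpeciesConfig(BaseModel):
    name: str
    temperatures: list[float]
    pigment: PigmentConfig = Field(default_factory=PigmentConfig)
    capacity: float | None = None  # override; defaults to the pigment's
    amin_source: Literal["measured", "predicted"] = "measured"
    mo2_ref: float | None = None  # demand (mmol O2 kg-1 h-1) at temperatures[0]

    @model_validator(mode="after")
    def _check(self) -> "SpeciesConfig":
        if not self.temperatures:
            raise ValueError(f"species {self.name}: needs >= 1 temperature")
        return self


class ProtocolConfig(BaseModel):
    po2_levels: list[float] = [21.0, 13.0, 4.0, 1.0]
    ph_range: tuple[float, float] = (8.1, 6.8)
    sample_interval: float = 30.0
    cal_segments: tuple[float, float] = (300.0, 300.0)
    ramp_duration: float = 1800.0

    def build(self, temperature: float) -> syn.ChamberProtocol:
        return syn.ChamberProtocol(
            po2_levels=tuple(self.po2_levels),
            ph_range=self.ph_range,
            temperature=temperature,
            sample_interval=self.sample_interval,
            cal_segments=self.cal_segments,
            ramp_duration=self.ramp_duration,
        )


class NoiseConfig(BaseModel):
    abs_sd: float = 0.005
    ph_sd: float = 0.005
    max_drift_rate: float = -0.02
    ph_scale_offset: float = 0.136


class AlphaStatConfig(BaseModel):
    slope: float = -0.0153
    anchor_ph: float = 7.42
    anchor_temp: float = 0.0

    def build(self) -> tx.AlphaStatModel:
        return tx.AlphaStatModel(self.slope, self.anchor_ph, self.anchor_temp)


class StudyConfig(BaseModel):
    species: list[SpeciesConfig]
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    alpha_stat: AlphaStatConfig = Field(default_factory=AlphaStatConfig)
    venous_po2_levels: list[float] = [4.0, 1.0]
    n_boot: int = 200
    seed: int = 0
    q10: float = 2.12
    blood_volume_frac: float = 0.052

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All study outputs plus provenance (config hash, seeds)."""

    binding_params: pd.DataFrame
    transport: pd.DataFrame
    circulation: pd.DataFrame
    errors: list[str]
    provenance: dict[str, Any]


def _measured_amin(trace: syn.ChamberTrace) -> float:
    n2 = trace.segment("n2_cal")
    if n2.empty:
        raise BluesatError("no n2_cal segment for a measured minimum signal")
    return float(n2["a347"].median())


def _process_species_temp(
    sp: SpeciesConfig,
    temp: float,
    config: StudyConfig,
) -> tuple[list[cv.PHOxygenCurve], float]:
    """Simulate and process one species at one temperature -> fitted curves."""
    gt = sp.pigment.build()
    protocol = config.protocol.build(temp)
    seed = substream_seed(config.seed, f"sim:{sp.name}:{temp}")
    noise = syn.NoiseModel(seed=seed, **config.noise.model_dump())
    traces = syn.simulate_chamber_experiment(gt, protocol, noise)
    curves = []
    for i, trace in enumerate(traces):
        amax0, drift = tp.calibrate_max_signal(trace)
        if sp.amin_source == "predicted":
            amin, _band = tp.predict_min_signal(trace.amin_true, (0.0, 1.0))
            source = "predicted"
        else:
            amin = _measured_amin(trace)
            source = "measured"
        cal = tp.CalibrationModel(
            amax0=amax0,
            amax_drift=drift,
            amin=amin,
            ph_offset=noise.ph_scale_offset,
            source=source,
        )
        series = tp.compute_saturation(trace, cal)
        fit_seed = substream_seed(config.seed, f"fit:{sp.name}:{temp}:{trace.po2}")
        curves.append(cv.fit_5pl(series, n_boot=config.n_boot, seed=fit_seed))
    capacity = sp.capacity if sp.capacity is not None else gt.capacity
    return curves, capacity


def run_study(config: StudyConfig) -> RunReport:
    """Execute the full pipeline for every species in the config.

    Failures are collected per species/temperature (with context) without
    aborting the other species; undefined quantities (e.g. a pH50 when the
    residual saturation exceeds 50%) appear as NaN, not as errors.
    """
    alpha = config.alpha_stat.build()
    binding_rows: list[dict[str, Any]] = []
    budget_rows: list[dict[str, Any]] = []
    circ_rows: list[dict[str, Any]] = []
    errors: list[str] = []

    for sp in config.species:
        curves_by_temp: dict[float, list[cv.PHOxygenCurve]] = {}
        capacity = sp.pigment.capacity if sp.capacity is None else sp.capacity
        for temp in sp.temperatures:
            try:
                curves_by_temp[temp], capacity = _process_species_temp(sp, temp, config)
            except BluesatError as exc:
                errors.append(f"{sp.name} @ {temp} degC: {exc}")
                log.warning("%s @ %s degC failed: %s", sp.name, temp, exc)
        if not curves_by_temp:
            continue
        all_curves = [c for cs in curves_by_temp.values() for c in cs]
        try:
            pooled_bohr = cv.bohr_coefficient(all_curves)
        except BluesatError as exc:
            pooled_bohr = float("nan")
            errors.append(f"{sp.name}: Bohr coefficient undefined ({exc})")

        p50_by_temp: dict[float, float] = {}
        for temp, curves in sorted(curves_by_temp.items()):
            vph = tx.venous_ph(alpha, temp)
            ph50s = {}
            for c in curves:
                try:
                    ph50s[c.po2] = cv.ph50(c)
                except PH50Undefined:
                    ph50s[c.po2] = float("nan")
            try:
                slope = None if np.isnan(pooled_bohr) else pooled_bohr
                p50_v = cv.p50_at_ph(curves, vph, slope=slope)
            except BluesatError:
                p50_v = float("nan")
            p50_by_temp[temp] = p50_v
            coop = float(np.mean([cv.cooperativity(c, capacity) for c in curves]))
            binding_rows.append(
                {
                    "species": sp.name,
                    "temperature": temp,
                    "venous_ph": vph,
                    "p50_kpa": p50_v,
                    "bohr": pooled_bohr,
                    "cooperativity": coop,
                    "capacity_mmol_l": capacity,
                    "hc_mg_ml": tx.hc_concentration(capacity),
                    **{f"ph50_{po2:g}kpa": v for po2, v in sorted(ph50s.items())},
                }
            )
            for v_po2 in config.venous_po2_levels:
                try:
                    cond = tx.InVivoConditions.at_temperature(
                        temp, alpha_stat=alpha, venous_po2=v_po2
                    )
                    budget = tx.transport_budget(curves, capacity, cond)
                except (BluesatError, ValueError) as exc:
                    errors.append(f"{sp.name} @ {temp} degC, venous {v_po2} kPa: {exc}")
                    continue
                budget_rows.append(
                    {
                        "species": sp.name,
                        "temperature": temp,
                        "venous_po2_kpa": v_po2,
                        **{k: getattr(budget, k) for k in budget.__dataclass_fields__},
                    }
                )
        # temperature sensitivity between coldest and warmest analysed temps
        temps_sorted = sorted(p50_by_temp)
        if len(temps_sorted) >= 2:
            t_lo, t_hi = temps_sorted[0], temps_sorted[-1]
            if np.isfinite(p50_by_temp[t_lo]) and np.isfinite(p50_by_temp[t_hi]):
                dp50 = (p50_by_temp[t_hi] - p50_by_temp[t_lo]) / (t_hi - t_lo)
                for row in binding_rows:
                    if row["species"] == sp.name:
                        row["dp50_dt_kpa_per_degc"] = dp50
        if sp.mo2_ref is not None and len(temps_sorted) >= 2:
            delivered = {
                r["temperature"]: r["bound_release"]
                for r in budget_rows
                if r["species"] == sp.name
                and r["venous_po2_kpa"] == 4.0
                and r["bound_release"] > 0
            }
            if len(delivered) >= 2:
                scen = circ.CirculationScenario(
                    mo2_ref=sp.mo2_ref,
                    t_ref=sp.temperatures[0],
                    delivered_per_l=delivered,
                    q10=config.q10,
                    blood_volume_frac=config.blood_volume_frac,
                )
                df = circ.run_scenario(scen)
                t_lo, t_hi = min(delivered), max(delivered)
                const_pct, meas_pct = circ.circulation_increase(
                    df.loc[df.temperature == t_lo, "mo2_mmol_kg_h"].iloc[0],
                    df.loc[df.temperature == t_hi, "mo2_mmol_kg_h"].iloc[0],
                    delivered[t_lo],
                    delivered[t_hi],
                )
                df["species"] = sp.name
                df["increase_constant_supply_pct"] = const_pct
                df["increase_measured_supply_pct"] = meas_pct
                circ_rows.append(df)

    report = RunReport(
        binding_params=pd.DataFrame(binding_rows),
        transport=pd.DataFrame(budget_rows),
        circulation=(
            pd.concat(circ_rows, ignore_index=True) if circ_rows else pd.DataFrame()
        ),
        errors=errors,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_boot": config.n_boot,
        },
    )
    return report


def _round_frame(df: pd.DataFrame, ndigits: int = 4) -> list[dict[str, Any]]:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(ndigits)
    return out.to_dict(orient="records")


def report_payload(report: RunReport) -> dict[str, Any]:
    """JSON-ready payload: full-precision tables plus display-rounded copies."""
    return {
        "provenance": report.provenance,
        "errors": report.errors,
        "binding_params": report.binding_params.to_dict(orient="records"),
        "transport": report.transport.to_dict(orient="records"),
        "circulation": report.circulation.to_dict(orient="records"),
        "display": {
            "binding_params": _round_frame(report.binding_params),
            "transport": _round_frame(report.transport),
        },
    }


def _check_node(obj: Any, schema: dict[str, Any], path: str, problems: list[str]) -> None:
    typ = schema.get("type")
    if typ == "object":
        if not isinstance(obj, dict):
            problems.append(f"{path}: expected object")
            return
        for key in schema.get("required", []):
            if key not in obj:
                problems.append(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check_node(obj[key], sub, f"{path}.{key}", problems)
    elif typ == "array":
        if not isinstance(obj, list):
            problems.append(f"{path}: expected array")
            return
        if "items" in schema:
            for i, item in enumerate(obj):
                _check_node(item, schema["items"], f"{path}[{i}]", problems)
    elif typ == "number":
        if not isinstance(obj, (int, float)) or isinstance(obj, bool):
            if obj is not None:  # NaN-as-null allowed for undefined cells
                problems.append(f"{path}: expected number, got {type(obj).__name__}")
    elif typ == "string":
        if not isinstance(obj, str):
            problems.append(f"{path}: expected string")


def validate_report_payload(payload: dict[str, Any]) -> None:
    """Structural validation against the shipped report schema; raises ValueError."""
    schema = json.loads(
        resources.files("bluesat").joinpath("report_schema.json").read_text()
    )
    problems: list[str] = []
    _check_node(payload, schema, "$", problems)
    if problems:
        raise ValueError("report payload invalid: " + "; ".join(problems))


def write_report(report: RunReport, outdir: str | Path, formats: tuple[str, ...] = ("csv", "json")) -> list[Path]:
    """Write the report tables with stable column order; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "csv" in formats:
        for name, df in (
            ("binding_params", report.binding_params),
            ("transport", report.transport),
            ("circulation", report.circulation),
        ):
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.10g")
            written.append(path)
    if "json" in formats:
        payload = report_payload(report)
        validate_report_payload(payload)
        path = outdir / "report.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))
        written.append(path)
    return written


def default_study_config(seed: int = 0, n_boot: int = 200) -> StudyConfig:
    """Three-species study with Table-1-like pigment anchors.

    Ground-truth P50/Bohr anchors follow the analysed species (Antarctic
    P. charcoti, SE-Australian O. pallidus, Mediterranean E. moschata);
    temperature coefficients are linear interpolations between each
    species' endpoint affinities at its alpha-stat venous pHs.
    """
    return StudyConfig(
        seed=seed,
        n_boot=n_boot,
        species=[
            SpeciesConfig(
                name="P_charcoti",
                temperatures=[0.0, 10.0],
                amin_source="predicted",
                mo2_ref=0.63,
                pigment=PigmentConfig(
                    capacity=1.58,
                    bohr_slope=-1.22,
                    p50_ref=2.34,
                    ph_ref=7.27,
                    temp_coeff=0.1715,
                    ref_temp=10.0,
                    lower_asymptote=0.0,
                    lower_asymptote_dT=-0.0336,
                ),
            ),
            SpeciesConfig(
                name="O_pallidus",
                temperatures=[10.0, 15.0, 20.0],
                pigment=PigmentConfig(
                    capacity=1.13,
                    bohr_slope=-1.97,
                    p50_ref=1.63,
                    ph_ref=7.27,
                    temp_coeff=0.131,
                    ref_temp=10.0,
                ),
            ),
            SpeciesConfig(
                name="E_moschata",
                temperatures=[10.0, 15.0, 20.0],
                pigment=PigmentConfig(
                    capacity=1.08,
                    bohr_slope=-1.88,
                    p50_ref=0.56,
                    ph_ref=7.27,
                    temp_coeff=0.0751,
                    ref_temp=10.0,
                ),
            ),
        ],
    )
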