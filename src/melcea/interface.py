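"""Run configuration, end-to-end orchestration, and report writers.

A run config (JSON) names the strategy parameter files, the digitized KM
input pairs per arm and endpoint, the life table, horizon, willingness to
pay, and the comparator. :func:`run_full_analysis` executes the pipeline —
reconstruct → fit → select → blend → trace → accumulate → compare, with
optional tornado/PSA/CEAC stages — and writes all tabular outputs plus a
provenance block sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .economics import (
    CEAResult,
    Comparison,
    DiscountRates,
    SocietalCosts,
    StrategySpec,
    SubsequentTreatment,
    Utilities,
    WeightBasedDrug,
    accumulate,
    compare,
)
from .markov_engine import CycleSchedule, derive_occupancy
from .sensitivity import (
    ModelBundle,
    compute_ceac,
    parameterize_distribution,
    run_dsa,
    run_psa,
)
from .survival_models import (
    FAMILIES,
    KMCurve,
    LifeTable,
    SurvivalCurveModel,
    blend_background_mortality,
    fit_all_families,
    reconstruct_interval_data,
    select_best_fit,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "ConfigError",
    "validate_config",
    "load_config",
    "strategy_spec_from_dict",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration invalid; ``errors`` lists every violation found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


@dataclass
class KMFilePair:
    survival: Path
    at_risk: Path


@dataclass
class RunConfig:
    """Validated end-to-end run description."""

    strategies: dict[str, StrategySpec]
    curve_sources: dict[str, dict[str, str]]  # strategy -> {"rfs": arm, "os": arm}
    comparator: str
    km_inputs: dict[str, dict[str, KMFilePair]]  # arm -> endpoint -> file pair
    life_table_path: Optional[Path]
    horizon_months: Optional[float]  # None = lifetime
    wtp: float
    output_dir: Path
    seed: int
    start_age: float
    family_override: Optional[str]
    sensitivity: bool
    n_draws: int
    price_year: int
    raw: dict = field(default_factory=dict, repr=False)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced, with provenance."""

    results: dict[str, CEAResult]
    comparisons: dict[str, Comparison]
    fit_reports: dict[str, dict]
    tornado: dict[str, pd.DataFrame]
    psa_draws: Optional[pd.DataFrame]
    ceac: Optional[pd.DataFrame]
    output_files: list[Path]
    provenance: dict


def strategy_spec_from_dict(raw: dict, errors: list[str]) -> Optional[StrategySpec]:
    """Build a StrategySpec from a JSON-style dict, collecting schema errors."""
    try:
        name = raw["name"]
        sched = raw["schedule"]
        schedule = CycleSchedule(
            cycle_length_weeks=float(sched["cycle_length_weeks"]),
            treatment_duration_cap_months=float(
                sched.get("treatment_duration_cap_months", 12.0)
            ),
            scan_schedule=tuple(
                tuple(map(float, s))
                for s in sched.get("scan_schedule", ((0, 24, 3), (24, 60, 6)))
            ),
        )
        weight_based = None
        if raw.get("rpd_weight_based"):
            weight_based = WeightBasedDrug(**raw["rpd_weight_based"])
        spec = StrategySpec(
            name=name,
            schedule=schedule,
            drug_cost_per_cycle=float(raw.get("drug_cost_per_cycle", 0.0)),
            admin_cost_per_cycle=float(raw.get("admin_cost_per_cycle", 0.0)),
            scan_cost_per_event=float(raw.get("scan_cost_per_event", 0.0)),
            ned_cost_per_year=float(raw.get("ned_cost_per_year", 0.0)),
            rpd_cost_per_year=float(raw.get("rpd_cost_per_year", 0.0)),
            bsc_cost_per_patient_entering_rpd=float(
                raw.get("bsc_cost_per_patient_entering_rpd", 0.0)
            ),
            subsequent_treatments=[
                SubsequentTreatment(**st) for st in raw.get("subsequent_treatments", [])
            ],
            rpd_weight_based=weight_based,
            societal=SocietalCosts(**raw.get("societal", {})),
            utilities=Utilities(**raw.get("utilities", {})),
            discount=DiscountRates(**raw.get("discount", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"strategy file invalid: {exc!r}")
        return None
    errors.extend(spec.validation_errors())
    return spec


def validate_config(raw: dict, base_dir: Path | str = ".") -> RunConfig:
    """Validate a raw config document, reporting every violation at once.

    Defaults: WTP EUR 50 000/QALY, discount rates 4.0%/1.5% (inside each
    strategy spec), lifetime horizon, median start age 50, log-normal family
    override, seed 0.
    """
    base = Path(base_dir)
    errors: list[str] = []

    strategies: dict[str, StrategySpec] = {}
    curve_sources: dict[str, dict[str, str]] = {}
    for entry in raw.get("strategies", []):
        path = base / entry
        if not path.exists():
            errors.append(f"strategy file not found: {path}")
            continue
        doc = json.loads(path.read_text())
        spec = strategy_spec_from_dict(doc, errors)
        if spec is None:
            continue
        if spec.name in strategies:
            errors.append(f"duplicate strategy name: {spec.name}")
        strategies[spec.name] = spec
        curve_sources[spec.name] = {
            "rfs": doc.get("rfs_source", spec.name),
            "os": doc.get("os_source", spec.name),
        }
    if not strategies:
        errors.append("no valid strategies configured")

    comparator = raw.get("comparator")
    if comparator is None:
        errors.append("comparator missing")
    elif strategies and comparator not in strategies:
        errors.append(f"comparator {comparator!r} not among strategies")

    km_inputs: dict[str, dict[str, KMFilePair]] = {}
    for arm, endpoints in raw.get("km_inputs", {}).items():
        km_inputs[arm] = {}
        for endpoint, pair in endpoints.items():
            if endpoint not in ("rfs", "os"):
                errors.append(f"km_inputs[{arm}]: unknown endpoint {endpoint!r}")
                continue
            fp = KMFilePair(base / pair["survival"], base / pair["at_risk"])
            for p in (fp.survival, fp.at_risk):
                if not p.exists():
                    errors.append(f"KM input not found: {p}")
            km_inputs[arm][endpoint] = fp
    for name, sources in curve_sources.items():
        for endpoint, arm in sources.items():
            if km_inputs and (arm not in km_inputs or endpoint not in km_inputs.get(arm, {})):
                errors.append(
                    f"strategy {name}: no KM input for arm {arm!r} endpoint {endpoint!r}"
                )

    life_table_path = None
    if raw.get("life_table"):
        life_table_path = base / raw["life_table"]
        if not life_table_path.exists():
            errors.append(f"life table not found: {life_table_path}")

    horizon = raw.get("horizon", "lifetime")
    horizon_months: Optional[float] = None
    if horizon != "lifetime":
        try:
            horizon_months = float(horizon["years"]) * 12.0
            if horizon_months <= 0:
                errors.append("horizon years must be positive")
        except (TypeError, KeyError, ValueError):
            errors.append(f"horizon must be 'lifetime' or {{'years': N}}, got {horizon!r}")

    wtp = float(raw.get("wtp", 50_000.0))
    if wtp < 0:
        errors.append("wtp must be non-negative")
    family_override = raw.get("family_override", "lognormal")
    if family_override is not None and family_override not in FAMILIES:
        errors.append(f"unknown family_override {family_override!r}")
    seed = int(raw.get("seed", 0))
    start_age = float(raw.get("start_age", 50.0))

    if errors:
        raise ConfigError(errors)

    return RunConfig(
        strategies=strategies,
        curve_sources=curve_sources,
        comparator=comparator,
        km_inputs=km_inputs,
        life_table_path=life_table_path,
        horizon_months=horizon_months,
        wtp=wtp,
        output_dir=base / raw.get("output_dir", "results"),
        seed=seed,
        start_age=start_age,
        family_override=family_override,
        sensitivity=bool(raw.get("sensitivity", False)),
        n_draws=int(raw.get("n_draws", 1000)),
        price_year=int(raw.get("price_year", 2020)),
        raw=raw,
    )


def load_config(path: Path | str) -> RunConfig:
    path = Path(path)
    return validate_config(json.loads(path.read_text()), base_dir=path.parent)


def fit_survival_inputs(config: RunConfig) -> tuple[dict, dict[str, SurvivalCurveModel]]:
    """Reconstruct, fit and select a survival model per (arm, endpoint).

    Returns (fit reports, curve models keyed ``"{arm}/{endpoint}"``). OS and
    RFS curves are both floored at background mortality when a life table is
    configured.
    """
    life_table = (
        LifeTable.from_csv(config.life_table_path) if config.life_table_path else None
    )
    reports: dict[str, dict] = {}
    models: dict[str, SurvivalCurveModel] = {}
    for arm, endpoints in config.km_inputs.items():
        for endpoint, pair in endpoints.items():
            curve = KMCurve.from_csv(
                pair.survival, pair.at_risk, endpoint=endpoint.upper(), arm_label=arm
            )
            data = reconstruct_interval_data(curve)
            fits = fit_all_families(data)
            best = select_best_fit(fits, override=config.family_override)
            reports[f"{arm}/{endpoint}"] = {
                "selected": best.family,
                "candidates": [f.to_dict() for f in fits],
            }
            if life_table is not None:
                model = blend_background_mortality(
                    best, life_table, start_age=config.start_age
                )
            else:
                model = SurvivalCurveModel.from_fit(best, start_age=config.start_age)
            models[f"{arm}/{endpoint}"] = model
    return reports, models


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute the configured pipeline end to end and write all outputs.

    Deterministic given the seed; every written file is listed in the report
    and the provenance block (config hash, seed, package version) is embedded
    in ``results.json``.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fit_reports, models = fit_survival_inputs(config)

    results: dict[str, CEAResult] = {}
    traces = {}
    for name, spec in config.strategies.items():
        src = config.curve_sources[name]
        try:
            rfs = models[f"{src['rfs']}/rfs"]
            os_model = models[f"{src['os']}/os"]
        except KeyError as exc:
            raise ConfigError([f"stage trace, strategy {name}: missing curve {exc}"])
        trace = derive_occupancy(
            rfs, os_model, spec.schedule, horizon_months=config.horizon_months
        )
        traces[name] = (rfs, os_model, trace)
        results[name] = accumulate(trace, spec)
        trace_path = out / f"trace_{name}.csv"
        trace.to_frame().to_csv(trace_path, index=False)
        written.append(trace_path)

    comparisons = {
        name: compare(res, results[config.comparator], wtp=config.wtp)
        for name, res in results.items()
        if name != config.comparator
    }

    tornado: dict[str, pd.DataFrame] = {}
    psa_frames = []
    ceac_frames = []
    if config.sensitivity:
        for name in comparisons:
            bundle = ModelBundle(
                strategy_spec=config.strategies[name],
                comparator_spec=config.strategies[config.comparator],
                strategy_curves=traces[name][:2],
                comparator_curves=traces[config.comparator][:2],
                horizon_months=config.horizon_months,
                wtp=config.wtp,
            )
            # Generic runs derive spreads from the configured base case.
            dists = [
                parameterize_distribution(
                    "adjuvant_drug_cost", "drug_cost_per_cycle", "gamma", 1.0,
                    scope="strategy", fraction=0.25, relative=True,
                ),
                parameterize_distribution(
                    "ned_state_cost", "ned_cost_per_year", "gamma", 1.0,
                    scope="both", fraction=0.25, relative=True,
                ),
                parameterize_distribution(
                    "rpd_state_cost", "rpd_cost_per_year", "gamma", 1.0,
                    scope="both", fraction=0.25, relative=True,
                ),
            ]
            entries = run_dsa(bundle, dists)
            tornado[name] = pd.DataFrame(
                {
                    "parameter": [e.parameter for e in entries],
                    "icer_low": [e.icer_at_low for e in entries],
                    "icer_high": [e.icer_at_high for e in entries],
                    "width": [e.width for e in entries],
                }
            )
            psa = run_psa(bundle, dists, n_draws=config.n_draws, seed=config.seed)
            psa_frames.append(psa.to_frame())
            curve = compute_ceac(psa)
            ceac_frames.append(
                pd.DataFrame(
                    {
                        "wtp": curve.wtp_grid,
                        "strategy": name,
                        "p_cost_effective": curve.probability_cost_effective,
                    }
                )
            )

    base_rows = pd.DataFrame([r.to_row() for r in results.values()])
    base_path = out / "base_case_table.csv"
    base_rows.to_csv(base_path, index=False)
    written.append(base_path)

    fits_path = out / "fits.json"
    fits_path.write_text(json.dumps(fit_reports, indent=2))
    written.append(fits_path)

    if tornado:
        for name, df in tornado.items():
            p = out / f"tornado_{name}.csv"
            df.to_csv(p, index=False)
            written.append(p)
    psa_df = pd.concat(psa_frames, ignore_index=True) if psa_frames else None
    if psa_df is not None:
        p = out / "psa_draws.csv"
        psa_df.to_csv(p, index=False)
        written.append(p)
    ceac_df = pd.concat(ceac_frames, ignore_index=True) if ceac_frames else None
    if ceac_df is not None:
        p = out / "ceac.csv"
        ceac_df.to_csv(p, index=False)
        written.append(p)

    try:
        version = metadata.version("melcea")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "version": version,
        "price_year": config.price_year,
    }
    results_doc = {
        "provenance": provenance,
        "results": {n: r.to_row() for n, r in results.items()},
        "comparisons": {n: c.to_row() for n, c in comparisons.items()},
    }
    results_path = out / "results.json"
    results_path.write_text(json.dumps(results_doc, indent=2, default=float))
    written.append(results_path)

    missing = [p for p in written if not p.exists()]
    if missing:  # pragma: no cover - defensive
        raise RuntimeError(f"report files missing on completion: {missing}")

    return RunReport(
        results=results,
        comparisons=comparisons,
        fit_reports=fit_reports,
        tornado=tornado,
        psa_draws=psa_df,
        ceac=ceac_df,
        output_files=written,
        provenance=provenance,
    )
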