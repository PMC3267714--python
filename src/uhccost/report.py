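"""Full-pipeline run: table-shaped CSV outputs, JSON summary, run manifest.

Every number written here is computed by an operation in the library
modules; this layer only formats.  Printed precision follows the reference
tables: INR as integers, USD to 0 dp, %GDP to 1 dp, ratios to 1 dp.
"""

from __future__ import annotations

import csv
import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .aggregate import scenario_cost_ratio
from .national import scale_cost_curve, scenario_increase_percent
from .params import load_parameters, serialize_registry
from .pipeline import build_outcome_model, run_base_case
from .sensitivity import probabilistic_sensitivity, univariate_sensitivity

__all__ = ["run_full_pipeline", "RunManifest"]


@dataclass(frozen=True)
class RunManifest:
    config_digest: str
    seed: int
    scenario: str
    timestamp_utc: str
    package_version: str
    python_version: str
    outputs: dict[str, str]  # filename -> sha256 of contents


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_pipeline(
    outputs_dir: str | Path,
    scenario: str = "generic",
    seed: int = 0,
    psa_draws: int = 1000,
) -> RunManifest:
    """Run demand, costing, premiums, national extrapolation, tornado and
    PSA for one drug scenario and write reports under ``outputs_dir``.

    Reruns with identical configuration and seed produce byte-identical
    numeric outputs (the manifest timestamp aside).
    """
    out = Path(outputs_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry, macro, profiles = load_parameters()
    result = run_base_case(scenario, registry, macro, profiles)

    # demand + cost table, reference-table shape
    with open(out / "demand_costs.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["specialty", "opd_visits_per_month", "ipd_bed_days_per_month",
                    "monthly_opd_cost_inr", "monthly_ipd_cost_inr"])
        for prof in profiles:
            o, i = result.specialty_costs.get(prof.name, (0.0, 0.0))
            w.writerow([prof.name,
                        result.demand.opd_visits_by_specialty[prof.name],
                        round(result.demand.bed_days_by_specialty[prof.name]),
                        round(o), round(i)])
        w.writerow(["surgical_package", "", "", "", round(result.summary.monthly_surgical)])

    other = run_base_case("branded" if scenario == "generic" else "generic",
                          registry, macro, profiles)
    branded, generic = ((other, result) if scenario == "generic"
                        else (result, other))
    summary = {
        "scenario": scenario,
        "monthly_patient_load": result.demand.monthly_load,
        "beds_required": result.demand.beds_required,
        "monthly_treatment_total_inr": round(result.monthly_treatment_total),
        "branded_to_generic_ratio": round(scenario_cost_ratio(
            branded.monthly_treatment_total, generic.monthly_treatment_total), 1),
        "annual_per_household_inr": round(result.summary.annual_per_household),
        "annual_per_person_inr": round(result.summary.annual_per_person),
        "branded_over_generic_increase_percent": scenario_increase_percent(
            branded.summary.annual_per_person, generic.summary.annual_per_person,
            macro.preventive_cost_per_capita_inr),
        "national": asdict(result.national),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    # scale curve: variable per-household cost from the scenario summary,
    # salaries+overhead amortized as the fixed hospital cost
    fixed = result.summary.monthly_salary + result.summary.monthly_overhead
    variable = 12.0 * (result.summary.monthly_treatment_opd
                       + result.summary.monthly_treatment_ipd
                       + result.summary.monthly_surgical) / 25_000.0
    with open(out / "scale_curve.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["beds", "efficient_population_million", "annual_per_household_inr"])
        for s in scale_cost_curve([100, 200, 300, 400, 500], fixed, variable):
            w.writerow([s.beds, s.efficient_population_million,
                        round(s.annual_per_household)])

    model = build_outcome_model(registry, profiles, macro, scenario,
                                outcome="household_premium")
    with open(out / "tornado.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["parameter", "outcome_at_low", "outcome_at_high", "swing"])
        for r in univariate_sensitivity(model, registry):
            w.writerow([r.parameter, round(r.outcome_at_low, 2),
                        round(r.outcome_at_high, 2), round(r.swing, 2)])

    psa = probabilistic_sensitivity(model, registry, n_draws=psa_draws, seed=seed)
    with open(out / "psa.csv", "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["n_draws", "seed", "mean", "percentile_2_5", "percentile_97_5"])
        w.writerow([psa.n_draws, psa.seed, round(psa.mean, 2),
                    round(psa.percentile_2_5, 2), round(psa.percentile_97_5, 2)])

    config_digest = hashlib.sha256(
        serialize_registry(registry).encode()).hexdigest()
    outputs = {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))}
    outputs["summary.json"] = _sha256(out / "summary.json")
    manifest = RunManifest(
        config_digest=config_digest,
        seed=seed,
        scenario=scenario,
        timestamp_utc=datetime.now(timezone.utc).isoformat(),
        package_version=__version__,
        python_version=platform.python_version(),
        outputs=outputs,
    )
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest
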