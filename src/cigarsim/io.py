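"""Scenario configuration files and report generation.

Scenarios are YAML documents:

.. code-block:: yaml

    model: mortality            # or: initiation
    inputs:                     # point inputs, keys per model kind
      attributable_deaths: 5200
    distributions:              # triangular triples, keys per model kind
      consumption_reduction: {min: 0.15, mode: 0.30, max: 0.45}
      cessation_fraction:    {min: 0.25, mode: 0.50, max: 0.75}
    simulation:
      n_iterations: 1000
      seed: 20160918
      interval_mass: 0.90

Two fixture files encoding the published nationwide US analyses ship
with the package (``bundled_scenario_path``).  Error categories are
distinct: a missing file raises :class:`FileNotFoundError`, a malformed
document :class:`ScenarioParseError`, and a structurally valid document
that violates model invariants :class:`ScenarioValidationError` listing
every offending key.

Reports apply the publication rounding rules — persons to the nearest
1,000, deaths to the nearest integer, percentages to one decimal — at
this layer only; all model arithmetic upstream is full precision.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .distributions import TriangularDist
from .engine import SimulationResult, SimulationSettings
from .errors import ScenarioValidationError
from .initiation import InitiationScenario
from .mortality import MortalityScenario

__all__ = [
    "ScenarioParseError",
    "load_scenario",
    "write_scenario",
    "bundled_scenario_path",
    "render_report",
    "round_persons",
    "round_deaths",
    "format_pct",
]


class ScenarioParseError(ValueError):
    """The scenario file is not a well-formed scenario document."""


_POINT_FIELDS = {
    "mortality": ("attributable_deaths", "machine_made_share", "flavored_retail_share"),
    "initiation": ("cohort_size", "current_use_prevalence",
                   "flavored_initiation_fraction", "continuing_prevalence_ratio"),
}
_DIST_FIELDS = {
    "mortality": ("consumption_reduction", "cessation_fraction"),
    "initiation": ("initiation_reduction", "continuing_reduction"),
}
_SCENARIO_CLS = {"mortality": MortalityScenario, "initiation": InitiationScenario}


def _parse_dist(key: str, raw, problems: list[str]) -> TriangularDist | None:
    if not isinstance(raw, dict) or set(raw) != {"min", "mode", "max"}:
        problems.append(f"distributions.{key} must be a mapping with keys min/mode/max")
        return None
    try:
        return TriangularDist(float(raw["min"]), float(raw["mode"]), float(raw["max"]))
    except (TypeError, ValueError) as exc:
        problems.append(f"distributions.{key}: {exc}")
        return None


def load_scenario(path) -> tuple[MortalityScenario | InitiationScenario, SimulationSettings]:
    """Read and validate a scenario file.

    Returns the scenario together with the file's simulation settings.
    Validation failures enumerate every offending key.
    """
    path = Path(path)
    text = path.read_text()  # missing file -> FileNotFoundError
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ScenarioParseError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ScenarioParseError(f"{path}: top level must be a mapping")
    kind = doc.get("model")
    if kind not in _SCENARIO_CLS:
        raise ScenarioParseError(
            f"{path}: 'model' must be one of {sorted(_SCENARIO_CLS)}, got {kind!r}")

    problems: list[str] = []
    inputs = doc.get("inputs") or {}
    dists = doc.get("distributions") or {}
    kwargs = {}
    for key in _POINT_FIELDS[kind]:
        if key not in inputs:
            problems.append(f"inputs.{key} is required for model '{kind}'")
        else:
            try:
                kwargs[key] = float(inputs[key])
            except (TypeError, ValueError):
                problems.append(f"inputs.{key} must be a number, got {inputs[key]!r}")
    for key in _DIST_FIELDS[kind]:
        if key not in dists:
            problems.append(f"distributions.{key} is required for model '{kind}'")
        else:
            d = _parse_dist(key, dists[key], problems)
            if d is not None:
                kwargs[key] = d
    unknown = (set(inputs) - set(_POINT_FIELDS[kind])) | (set(dists) - set(_DIST_FIELDS[kind]))
    for key in sorted(unknown):
        problems.append(f"unknown key '{key}' for model '{kind}'")
    if problems:
        raise ScenarioValidationError(problems)

    try:
        scenario = _SCENARIO_CLS[kind](**kwargs)
    except ScenarioValidationError:
        raise
    sim = doc.get("simulation") or {}
    settings = SimulationSettings(
        n_iterations=int(sim.get("n_iterations", 1000)),
        seed=int(sim.get("seed", 0)),
        interval_mass=float(sim.get("interval_mass", 0.90)),
    )
    return scenario, settings


def write_scenario(scenario, settings: SimulationSettings, path) -> Path:
    """Serialize a scenario + settings to YAML (inverse of load_scenario)."""
    path = Path(path)
    doc = scenario_document(scenario, settings)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def scenario_document(scenario, settings: SimulationSettings | None = None) -> dict:
    """The plain-dict YAML form of a scenario (used for writing and hashing)."""
    kind = scenario.model_kind
    doc = {
        "model": kind,
        "inputs": {k: float(getattr(scenario, k)) for k in _POINT_FIELDS[kind]},
        "distributions": {
            k: {"min": float(getattr(scenario, k).minimum),
                "mode": float(getattr(scenario, k).mode),
                "max": float(getattr(scenario, k).maximum)}
            for k in _DIST_FIELDS[kind]
        },
    }
    if settings is not None:
        doc["simulation"] = {
            "n_iterations": settings.n_iterations,
            "seed": settings.seed,
            "interval_mass": settings.interval_mass,
        }
    return doc


def scenario_hash(scenario) -> str:
    """Short content hash of a scenario, recorded in report headers."""
    canon = yaml.safe_dump(scenario_document(scenario), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def bundled_scenario_path(kind: str) -> Path:
    """Path of a packaged fixture scenario ('mortality' or 'initiation')."""
    if kind not in _SCENARIO_CLS:
        raise KeyError(f"no bundled scenario {kind!r}")
    return Path(resources.files("cigarsim") / "scenarios" / f"{kind}.yaml")


# --- reporting -----------------------------------------------------------

def round_persons(x: float) -> int:
    """Publication rounding for person counts: nearest 1,000."""
    return int(round(x / 1000.0) * 1000)


def round_deaths(x: float) -> int:
    """Publication rounding for death counts: nearest integer."""
    return int(round(x))


def format_pct(p: float) -> str:
    """Proportion -> percentage string with one decimal."""
    return f"{100.0 * p:.1f}%"


def _rounder(channel: str):
    return round_deaths if "deaths" in channel else round_persons


def _fmt(channel: str, x: float) -> str:
    return f"{_rounder(channel)(x):,}"


def render_report(scenario, settings: SimulationSettings, result: SimulationResult,
                  tornado_records: list[dict], outdir, fmt: str = "both",
                  stem: str | None = None) -> dict[str, Path]:
    """Write the plain-text summary and/or the results CSV for one run.

    Returns the paths written, keyed by format.  The CSV keeps full
    precision in ``value``/``low``/``high`` and applies publication
    rounding in ``reported``/``reported_low``/``reported_high``.
    """
    if fmt not in ("csv", "txt", "both"):
        raise ValueError(f"format must be csv, txt or both, got {fmt!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or scenario.model_kind
    from . import __version__

    header = (
        f"cigarsim {__version__} | model={scenario.model_kind} "
        f"| scenario sha256:{scenario_hash(scenario)} "
        f"| seed={settings.seed} iterations={settings.n_iterations} "
        f"| interval mass={settings.interval_mass:g}"
    )
    point = scenario.point_estimate()
    rows = []
    for channel, value in point.items():
        if channel == "prevalence_reduction":
            rows.append({"record_type": "point", "name": channel, "method": "modes",
                         "value": value, "low": "", "high": "", "n_bins": "",
                         "reported": format_pct(value), "reported_low": "",
                         "reported_high": ""})
            continue
        rows.append({"record_type": "point", "name": channel, "method": "modes",
                     "value": value, "low": "", "high": "", "n_bins": "",
                     "reported": _rounder(channel)(value), "reported_low": "",
                     "reported_high": ""})
    for channel in result.outputs:
        s = result.summary(channel)
        rows.append({
            "record_type": "simulation", "name": channel, "method": "monte_carlo",
            "value": s["mean"], "low": s["interval_low"], "high": s["interval_high"],
            "n_bins": "", "reported": _rounder(channel)(s["mean"]),
            "reported_low": _rounder(channel)(s["interval_low"]),
            "reported_high": _rounder(channel)(s["interval_high"]),
        })
    primary = result.primary
    for rec in tornado_records:
        rows.append({
            "record_type": "sensitivity", "name": rec["input_name"],
            "method": rec["method"], "value": "",
            "low": rec["low"], "high": rec["high"], "n_bins": rec["n_bins"],
            "reported": "", "reported_low": _rounder(primary)(rec["low"]),
            "reported_high": _rounder(primary)(rec["high"]),
        })

    written: dict[str, Path] = {}
    if fmt in ("csv", "both"):
        csv_path = outdir / f"{stem}_results.csv"
        df = pd.DataFrame(rows)
        with csv_path.open("w", newline="") as fh:
            fh.write(f"# {header}\n")
            df.to_csv(fh, index=False)
        written["csv"] = csv_path
    if fmt in ("txt", "both"):
        txt_path = outdir / f"{stem}_summary.txt"
        txt_path.write_text(_text_summary(scenario, settings, result,
                                          tornado_records, header))
        written["txt"] = txt_path
    return written


def _text_summary(scenario, settings, result, tornado_records, header) -> str:
    s = result.summary()
    primary = result.primary
    r = _rounder(primary)
    lines = [header, "=" * len(header), ""]
    point = scenario.point_estimate()
    if scenario.model_kind == "mortality":
        lines += [
            f"Point estimate: {scenario.attributable_deaths:,.0f} attributable deaths"
            f" x {format_pct(scenario.consumption_reduction.mode)} consumption reduction"
            f" x {format_pct(scenario.cessation_fraction.mode)} complete cessation"
            f" = {round_deaths(point['deaths_avoided']):,} premature deaths avoided each year.",
            "",
            f"Monte Carlo ({settings.n_iterations} iterations): mean "
            f"{r(s['mean']):,} deaths avoided, {format_pct(result.interval_mass)[:-1]}%"
            f" prediction interval {r(s['interval_low']):,} to {r(s['interval_high']):,}.",
        ]
    else:
        lines += [
            f"Flavored-initiate base: {scenario.cohort_size:,.0f} 18-year-olds"
            f" x {format_pct(scenario.current_use_prevalence)} current cigar use"
            f" x {format_pct(scenario.flavored_initiation_fraction)} flavored initiation"
            f" = {round_persons(scenario.base):,} persons.",
            f"Point estimate: {round_persons(point['initiates_prevented']):,} initiates"
            f" prevented + {round_persons(point['continuing_prevented']):,} continuing users"
            f" prevented = {round_persons(point['total_prevented']):,} total"
            f" ({format_pct(point['prevalence_reduction'])} reduction in current cigar"
            f" prevalence for the cohort).",
            "",
            f"Monte Carlo ({settings.n_iterations} iterations): mean "
            f"{r(s['mean']):,} current users prevented, "
            f"{format_pct(result.interval_mass)[:-1]}% prediction interval "
            f"{r(s['interval_low']):,} to {r(s['interval_high']):,}.",
        ]
    lines.append("")
    lines.append("One-way sensitivity (primary output):")
    for rec in tornado_records:
        lines.append(
            f"  {rec['input_name']:<24s} {rec['method']:<24s} "
            f"{r(rec['low']):,} to {r(rec['high']):,}")
    lines.append("")
    return "\n".join(lines)
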