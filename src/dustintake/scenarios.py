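"""Scenario configuration: YAML variable blocks and the packaged study data.

A scenario file declares the compound, route, ADI and three variable blocks
(``ingestion_rate``, ``concentration``, ``body_weight``).  Each block carries
a ``kind`` — ``moments``, ``percentiles``, ``censored_values`` or ``point`` —
plus the fields of that evidence type; blocks may carry both moments and a
percentile table, in which case the ``parameterization`` switch decides which
is fitted (moments by default, since the mean/SD pair is the only complete
summary printed for every concentration and ingestion-rate row of the source
survey tables).

Four scenario files ship with the package (chlorpyrifos/cypermethrin x
indoor dust/outdoor soil), reproducing the published summary table verbatim,
together with the external dietary-intake percentile tables used for route
comparison.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path

import yaml

from .distributions import (
    CensoredSample,
    LognormalSpec,
    PercentileTable,
    SummaryMoments,
    compare_fit_to_percentiles,
    fit_from_censored,
    fit_from_moments,
    fit_from_percentiles,
)
from .exposure import ADI_REGISTRY, CONVERSION_FACTOR, ExposureScenario
from .errors import ConfigError, DataError
from .reporting import ExternalPercentiles

__all__ = [
    "PACKAGED_SCENARIOS",
    "fit_variable_block",
    "load_scenario",
    "load_scenario_file",
    "load_dietary_table",
    "load_published_nondietary_total",
    "scenario_consistency",
]

PACKAGED_SCENARIOS = (
    "chlorpyrifos_dust",
    "chlorpyrifos_soil",
    "cypermethrin_dust",
    "cypermethrin_soil",
)

_DATA = resources.files("dustintake") / "data"


def _percentile_table(block: dict) -> PercentileTable:
    raw = block.get("percentiles")
    if not raw:
        raise ConfigError("variable block has no 'percentiles' entry")
    entries = sorted(
        (float(p), float(v)) for p, v in raw.items() if v is not None
    )
    if len(entries) < 2:
        raise ConfigError(
            "percentile parameterization needs >= 2 numeric percentile entries"
        )
    return PercentileTable(entries)


def fit_variable_block(
    block: dict, parameterization: str = "moments", unit: str | None = None
) -> LognormalSpec:
    """Fit one YAML variable block into a lognormal spec.

    ``parameterization`` applies only to blocks of kind ``moments`` that also
    print a percentile table; other kinds have a single natural fit.
    """
    if not isinstance(block, dict) or "kind" not in block:
        raise ConfigError("variable block must be a mapping with a 'kind' field")
    kind = block["kind"]
    unit = unit if unit is not None else block.get("unit", "")
    try:
        if kind == "moments":
            if parameterization == "percentiles" and block.get("percentiles"):
                return fit_from_percentiles(_percentile_table(block), unit_label=unit)
            summary = SummaryMoments(
                mean=float(block["mean"]), sd=float(block["sd"]), n=block.get("n")
            )
            return fit_from_moments(summary, unit_label=unit)
        if kind == "percentiles":
            return fit_from_percentiles(_percentile_table(block), unit_label=unit)
        if kind == "censored_values":
            sample = CensoredSample(
                values=block["values"],
                censored=block["censored"],
                lod=float(block["lod"]),
            )
            return fit_from_censored(sample, unit_label=unit)
        if kind == "point":
            return LognormalSpec.point_mass(float(block["value"]), unit_label=unit)
        if kind == "lognormal":
            sigma = float(block["sigma"])
            if sigma == 0.0:
                return LognormalSpec.point_mass(math.exp(float(block["mu"])), unit_label=unit)
            return LognormalSpec(mu=float(block["mu"]), sigma=sigma, unit_label=unit)
    except KeyError as exc:
        raise ConfigError(f"variable block of kind '{kind}' missing field {exc}") from exc
    raise ConfigError(f"unknown variable kind {kind!r}")


def _scenario_from_mapping(
    doc: dict, parameterization: str = "moments"
) -> ExposureScenario:
    for key in ("compound", "route", "ingestion_rate", "concentration", "body_weight"):
        if key not in doc:
            raise ConfigError(f"scenario file missing required field '{key}'")
    compound = str(doc["compound"])
    if "adi" in doc:
        adi = float(doc["adi"])
    elif compound in ADI_REGISTRY:
        adi = ADI_REGISTRY[compound]
    else:
        raise ConfigError(
            f"compound '{compound}' has no registered ADI; the scenario must state one"
        )
    return ExposureScenario(
        compound=compound,
        route=str(doc["route"]),
        ir=fit_variable_block(doc["ingestion_rate"], parameterization),
        conc=fit_variable_block(doc["concentration"], parameterization),
        bw=fit_variable_block(doc["body_weight"], parameterization),
        adi=adi,
        cf=float(doc.get("conversion_factor", CONVERSION_FACTOR)),
    )


def load_scenario_file(path, parameterization: str = "moments") -> ExposureScenario:
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return _scenario_from_mapping(doc, parameterization)


def load_scenario(name_or_path, parameterization: str = "moments") -> ExposureScenario:
    """Load a packaged scenario by name, or any scenario YAML by path."""
    if name_or_path in PACKAGED_SCENARIOS:
        with resources.as_file(_DATA / "scenarios" / f"{name_or_path}.yaml") as p:
            return load_scenario_file(p, parameterization)
    path = Path(name_or_path)
    if not path.exists():
        raise ConfigError(
            f"'{name_or_path}' is neither a packaged scenario "
            f"{PACKAGED_SCENARIOS} nor an existing file"
        )
    return load_scenario_file(path, parameterization)


def _external_csv(relative: str) -> ExternalPercentiles:
    with resources.as_file(_DATA / relative) as p:
        if not p.exists():
            raise ConfigError(f"no packaged table at data/{relative}")
        return ExternalPercentiles.from_csv(p)


def load_dietary_table(compound: str) -> ExternalPercentiles:
    """Published dietary-intake %ADI percentiles for a compound (external
    constants from a probabilistic vegetable-residue risk assessment; the
    package never recomputes dietary intake)."""
    return _external_csv(f"dietary_intake/{compound}.csv")


def load_published_nondietary_total(compound: str) -> ExternalPercentiles:
    """The source study's printed total non-dietary %ADI percentiles
    (dust + soil), kept as a packaged fixture for desk comparisons."""
    return _external_csv(f"published_totals/{compound}.csv")


def scenario_consistency(name_or_path, parameterization: str = "moments") -> dict:
    """Diagnose moment/percentile agreement of a scenario's variable blocks.

    For every block that prints both moments and percentiles, compares the
    fitted lognormal's quantiles with the printed percentiles and reports the
    maximum absolute relative error.  Survey tables are not always internally
    consistent with a single lognormal (a known feature of published summary
    tables); disagreement is flagged here, never silently corrected.
    """
    if name_or_path in PACKAGED_SCENARIOS:
        ctx = resources.as_file(_DATA / "scenarios" / f"{name_or_path}.yaml")
        with ctx as p, open(p) as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(name_or_path) as fh:
            doc = yaml.safe_load(fh)
    out = {}
    for var in ("ingestion_rate", "concentration", "body_weight"):
        block = doc.get(var)
        if not isinstance(block, dict):
            continue
        if block.get("kind") != "moments" or not block.get("percentiles"):
            continue
        spec = fit_variable_block(block, parameterization)
        try:
            table = _percentile_table(block)
        except (ConfigError, DataError):
            continue
        diag = compare_fit_to_percentiles(spec, table)
        diag["flagged"] = diag["max_abs_relative_error"] > 1.0
        out[var] = diag
    return out
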