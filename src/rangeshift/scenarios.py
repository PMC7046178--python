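"""Scenario codes and the catalog of standard experiments.

Codes follow the figure labels: species letter (A annual, P perennial,
T tree), adaptation mode (L locally adapted, P plastic, PW widely
plastic, LF locally adapted with halved climate penalties), then the mean
seed dispersal distance in meters, then an optional landscape/schedule
suffix:

* ``.L``  — shallow 8 km gradient (bands 4x wide, shift 80 m/yr);
* ``.F``  — fast shift (40 m/yr) on the standard landscape;
* ``.FE`` — fast shift on the extended landscape (coldest band 3x wide);
* ``.R+`` — restabilization 10x as long as standard.

Examples: ``AL.20``, ``PPW.20``, ``TL.40.F``, ``AP.1.R+``.
"""

from __future__ import annotations

from dataclasses import replace

from .demography import genetic_system, species_preset
from .engine import ScenarioConfig
from .landscape import landscape_variant

__all__ = ["parse_code", "scenario_catalog", "CATALOG_CODES"]

_SPECIES = {"A": "annual", "P": "perennial", "T": "tree"}
_MODES = {
    "L": ("locally_adapted", False),
    "P": ("plastic", False),
    "PW": ("widely_plastic", False),
    "LF": ("locally_adapted", True),
}
_POLLEN_MEANS = {"annual": 60.0, "perennial": 80.0, "tree": 180.0}
_VARIANTS = {"": "standard", "L": "shallow8km", "F": "fast", "FE": "fast_extended"}

CATALOG_CODES: tuple[str, ...] = (
    "AL.20", "AL.50",
    "AP.1", "AP.20", "AP.50", "AP.1.R+",
    "PL.20", "PL.80", "PP.20", "PP.80",
    "PPW.20", "PLF.20",
    "TL.40", "TL.80", "TP.40", "TP.80",
    "TL.40.L", "TL.80.L", "TP.40.L", "TP.80.L",
    "TL.40.F", "TL.80.F", "TP.40.F", "TP.80.F",
    "TL.40.FE", "TL.80.FE", "TP.40.FE", "TP.80.FE",
)


def parse_code(code: str, replicates: int = 4) -> ScenarioConfig:
    """Resolve a scenario code into a complete configuration."""
    parts = code.split(".")
    if len(parts) < 2:
        raise ValueError(f"malformed scenario code {code!r}")
    head, mean_s, *rest = parts
    if not head or head[0] not in _SPECIES:
        raise ValueError(f"unknown species letter in {code!r}")
    species_name = _SPECIES[head[0]]
    mode_token = head[1:]
    if mode_token not in _MODES:
        raise ValueError(f"unknown adaptation mode {mode_token!r} in {code!r}")
    mode, softened = _MODES[mode_token]
    try:
        seed_mean = float(mean_s)
    except ValueError:
        raise ValueError(f"bad dispersal mean {mean_s!r} in {code!r}") from None
    if seed_mean <= 0:
        raise ValueError("dispersal mean must be positive")

    restab_multiplier = 1
    variant_token = ""
    for token in rest:
        if token == "R+":
            restab_multiplier = 10
        elif token in _VARIANTS:
            variant_token = token
        else:
            raise ValueError(f"unknown scenario suffix {token!r} in {code!r}")

    species = species_preset(species_name)
    genetics = genetic_system(mode, softened=softened)
    spec, sched = landscape_variant(_VARIANTS[variant_token])
    equil = species.equilibration_years
    sched = replace(sched, shift_start_year=equil)
    return ScenarioConfig(
        code=code,
        species=species,
        genetics=genetics,
        seed_mean=seed_mean,
        pollen_mean=_POLLEN_MEANS[species_name],
        landscape=spec,
        climate=sched,
        equilibration_years=equil,
        shift_years=sched.shift_duration,
        restab_years=equil * restab_multiplier,
        replicates=replicates,
    )


def scenario_catalog(replicates: int = 4) -> dict[str, ScenarioConfig]:
    """All standard experiment configurations, keyed by code."""
    return {code: parse_code(code, replicates) for code in CATALOG_CODES}
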