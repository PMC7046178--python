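"""File output: yearly occupancy CSVs, phase-boundary grid snapshots and
run summaries, with the configuration echoed for provenance."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import PHASES, RunResult
from .metrics import allele_frequency_map, modal_genotype_map, summarize_run

__all__ = ["write_outputs"]


def _phase_of_year(result: RunResult, year: int) -> str:
    config = result.config
    if year <= config.phase_end_year("stable"):
        return "Stable"
    if year <= config.phase_end_year("shift"):
        return "Shift"
    return "Restab"


def _config_dict(result: RunResult) -> dict:
    c = result.config
    return {
        "code": c.code,
        "species": c.species.name,
        "genotypes": list(c.genetics.genotype_names),
        "seed_mean_m": c.seed_mean,
        "pollen_mean_m": c.pollen_mean,
        "kernel_shape_p": c.kernel_p,
        "landscape": {
            "n_rows": c.landscape.n_rows,
            "n_cols": c.landscape.n_cols,
            "patch_size_m": c.landscape.patch_size,
            "band_width": c.landscape.band_width,
            "cold_band_multiplier": c.landscape.cold_band_multiplier,
        },
        "climate": {
            "shift_start_year": c.climate.shift_start_year,
            "shift_duration": c.climate.shift_duration,
            "patches_per_year": c.climate.patches_per_year,
        },
        "years": {
            "equilibration": c.equilibration_years,
            "shift": c.shift_years,
            "restabilization": c.restab_years,
        },
        "replicates": c.replicates,
        "rng_seed": result.seed,
    }


def write_outputs(result: RunResult, out_dir: str | Path) -> Path:
    """Write a run's CSV time series, snapshot grids and summary.

    Layout under ``out_dir``::

        config.json                      scenario + seed echo
        occupancy.csv                    per replicate/year/genotype
        summary.csv                      phase means +/- SD over replicates
        snapshots/rep<k>_<phase>_<layer>.csv   grid matrices

    Snapshot layers are per genotype x stage adult counts plus the
    modal-genotype and allele-frequency maps.  Deterministic for a fixed
    (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = result.config
    genetics, species = config.genetics, config.species
    total = config.landscape.n_patches

    (out / "config.json").write_text(json.dumps(_config_dict(result), indent=2) + "\n")

    labels = ["species"] + list(genetics.genotype_names)
    rows = []
    for rep in range(result.occupancy.shape[0]):
        for year in range(result.occupancy.shape[1]):
            phase = _phase_of_year(result, year)
            for j, label in enumerate(labels):
                patches = int(result.occupancy[rep, year, j])
                rows.append(
                    {
                        "replicate": rep,
                        "year": year,
                        "phase": phase,
                        "genotype": label,
                        "patches": patches,
                        "percent": 100.0 * patches / total,
                    }
                )
    pd.DataFrame(rows).to_csv(out / "occupancy.csv", index=False)

    summarize_run(result).table.to_csv(out / "summary.csv", index=False)

    snap_dir = out / "snapshots"
    snap_dir.mkdir(exist_ok=True)
    for (rep, phase), snap in sorted(result.snapshots.items()):
        counts = snap["counts"]
        for s, stage in enumerate(species.stage_names):
            for g, gname in enumerate(genetics.genotype_names):
                layer = counts[s, g]
                if layer.any():
                    np.savetxt(
                        snap_dir / f"rep{rep}_{phase}_{stage}_{gname}.csv",
                        layer,
                        fmt="%d",
                        delimiter=",",
                    )
        modal = modal_genotype_map(counts, species)
        np.savetxt(snap_dir / f"rep{rep}_{phase}_modal_genotype.csv", modal, fmt="%d", delimiter=",")
        freqs = allele_frequency_map(counts, species, genetics)
        for a, allele in enumerate(genetics.allele_labels):
            np.savetxt(
                snap_dir / f"rep{rep}_{phase}_freq_{allele}.csv",
                freqs[a],
                fmt="%.4f",
                delimiter=",",
            )
    return out
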