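"""Occupancy, range-change and genotype/allele map metrics.

A patch counts as occupied when it holds at least one *reproductive
adult* (annual adults; perennial or tree small/medium/large adults);
seedlings and saplings do not establish occupancy.  Range change between
two timepoints is the signed percent change in occupied patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import GeneticSystem, StageSchedule
from .engine import PHASES, RunResult

__all__ = [
    "adult_counts",
    "occupancy",
    "percent_change",
    "allele_frequency_map",
    "modal_genotype_map",
    "OccupancySummary",
    "summarize_run",
]


def adult_counts(counts: np.ndarray, schedule: StageSchedule) -> np.ndarray:
    """(G, R, C) reproductive-adult counts from a (S, G, R, C) state array."""
    return counts[schedule.reproductive].sum(axis=0)


def occupancy(counts: np.ndarray, schedule: StageSchedule) -> tuple[int, np.ndarray]:
    """Patches occupied by adults: (species total, per-genotype array)."""
    adults = adult_counts(counts, schedule)
    per_genotype = (adults > 0).sum(axis=(1, 2))
    species = int((adults.sum(axis=0) > 0).sum())
    return species, per_genotype


def percent_change(occ_start: float, occ_end: float) -> float:
    """Signed percent change; negative = range loss.  Undefined (NaN) when
    the starting occupancy is zero."""
    if occ_start == 0:
        return float("nan")
    return 100.0 * (occ_end - occ_start) / occ_start


def allele_frequency_map(counts: np.ndarray, schedule: StageSchedule, genetics: GeneticSystem) -> np.ndarray:
    """(n_alleles, R, C) allele frequencies among established individuals.

    Every established (non-seed) individual contributes two allele copies;
    empty patches are NaN.
    """
    established = counts.sum(axis=0).astype(float)  # (G, R, C)
    copies = np.tensordot(genetics.dosage.T, established, axes=(1, 0))  # (A, R, C)
    total = copies.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, copies / np.where(total > 0, total, 1.0), np.nan)
    return freq


def modal_genotype_map(counts: np.ndarray, schedule: StageSchedule) -> np.ndarray:
    """(R, C) index of the most common genotype among adults per patch.

    Ties break toward the lower genotype index (canonical allele-pair
    order); empty patches are -1.
    """
    adults = adult_counts(counts, schedule)
    modal = np.argmax(adults, axis=0)
    modal[adults.sum(axis=0) == 0] = -1
    return modal


@dataclass(frozen=True)
class OccupancySummary:
    """Replicate mean and SD of occupancy at each phase boundary."""

    table: pd.DataFrame  # columns: phase, label, mean, sd, percent_mean, percent_sd


def summarize_run(result: RunResult) -> OccupancySummary:
    """Fig.-4-style summary: per-phase species and genotype occupancy,
    mean +/- SD over replicates, plus percent of landscape."""
    config = result.config
    total_patches = config.landscape.n_patches
    labels = ["species"] + list(config.genetics.genotype_names)
    rows = []
    for phase in PHASES:
        if config.phase_end_year(phase) >= result.occupancy.shape[1]:
            continue
        occ = result.occupancy[:, config.phase_end_year(phase), :]  # (reps, 1+G)
        for j, label in enumerate(labels):
            vals = occ[:, j].astype(float)
            rows.append(
                {
                    "phase": phase.capitalize(),
                    "label": label,
                    "mean_patches": vals.mean(),
                    "sd_patches": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                    "percent_mean": 100.0 * vals.mean() / total_patches,
                    "percent_sd": (100.0 * vals.std(ddof=1) / total_patches) if len(vals) > 1 else 0.0,
                }
            )
    return OccupancySummary(table=pd.DataFrame(rows))
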