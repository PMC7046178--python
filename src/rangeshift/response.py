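"""Genotypes, climate optima and climate-effect (ClimEff) response curves.

Adaptation to climate is governed by a single diploid locus with three
alleles A1 < A2 < A3 on the climate-zone scale (A1 is cold-adapted).  The
three alleles yield six genotypes; a heterozygote's optimum climate is the
arithmetic mean of the corresponding homozygotes' optima.  Every maximum
demographic rate of a genotype is multiplied by ClimEff, a value in [0, 1]
that declines with the distance between the genotype's optimum and the
local climate zone.

Two kinds of curve are supported:

* distance-indexed tables (the locally adapted genotypes and the standard
  plastic genotype), evaluated at |optimum - zone| with linear
  interpolation at fractional distances and 0 beyond the table;
* zone-indexed tables (the hypothetical "widely plastic" genotype, whose
  fitness at each zone is the pointwise maximum over all locally adapted
  genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlleleSet",
    "GenotypeDef",
    "ResponseCurve",
    "DEFAULT_ALLELES",
    "LOCALLY_ADAPTED_CURVE",
    "PLASTIC_CURVE",
    "genotype_optimum",
    "clim_eff",
    "soften_curve",
    "widely_plastic_curve",
    "six_genotypes",
]


@dataclass(frozen=True)
class AlleleSet:
    """Allele labels mapped to their climate values (zone scale)."""

    climate_values: dict[str, float] = field(
        default_factory=lambda: {"A1": 4.0, "A2": 6.0, "A3": 8.0}
    )

    def __post_init__(self) -> None:
        vals = list(self.climate_values.values())
        if sorted(vals) != vals or len(set(vals)) != len(vals):
            raise ValueError("allele climate values must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.climate_values)

    def value(self, allele: str) -> float:
        try:
            return self.climate_values[allele]
        except KeyError:
            raise KeyError(f"unknown allele {allele!r}") from None


DEFAULT_ALLELES = AlleleSet()


@dataclass(frozen=True)
class GenotypeDef:
    """An unordered diploid allele pair."""

    alleles: tuple[str, str]

    @property
    def name(self) -> str:
        return "".join(self.alleles)

    def optimum(self, allele_set: AlleleSet) -> float:
        a, b = self.alleles
        return 0.5 * (allele_set.value(a) + allele_set.value(b))

    @property
    def is_heterozygote(self) -> bool:
        return self.alleles[0] != self.alleles[1]


def genotype_optimum(genotype: GenotypeDef, alleles: AlleleSet = DEFAULT_ALLELES) -> float:
    """Optimum climate of a genotype: the mean of its alleles' climate values."""
    return genotype.optimum(alleles)


def six_genotypes(alleles: AlleleSet = DEFAULT_ALLELES) -> tuple[GenotypeDef, ...]:
    """All unordered pairs from the allele set, in canonical sorted order."""
    labels = alleles.labels
    pairs = []
    for i, a in enumerate(labels):
        for b in labels[i:]:
            pairs.append(GenotypeDef((a, b)))
    return tuple(pairs)


@dataclass(frozen=True)
class ResponseCurve:
    """ClimEff multiplier as a function of climate distance (or zone).

    ``table[d]`` gives the multiplier ``d`` integer steps from the optimum;
    fractional distances are linearly interpolated and distances beyond the
    table evaluate to 0.  With ``zone_indexed=True`` the table is indexed
    directly by climate zone starting at ``zone_origin`` and the optimum
    argument is ignored.
    """

    table: tuple[float, ...]
    zone_indexed: bool = False
    zone_origin: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("table must be a non-empty 1-D sequence")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("ClimEff values must lie in [0, 1]")
        if not self.zone_indexed:
            if arr[0] != 1.0:
                raise ValueError("ClimEff at distance 0 must be 1")
            if np.any(np.diff(arr) > 1e-12):
                raise ValueError("ClimEff must be weakly decreasing in distance")

    def at_distance(self, d):
        """Evaluate at non-negative distance(s), interpolating linearly."""
        d = np.abs(np.asarray(d, dtype=float))
        xp = np.arange(len(self.table), dtype=float)
        out = np.interp(d, xp, np.asarray(self.table, dtype=float), right=0.0)
        return out if out.shape else float(out)

    def at_zone(self, optimum: float, zone):
        if self.zone_indexed:
            z = np.asarray(zone, dtype=float) - self.zone_origin
            xp = np.arange(len(self.table), dtype=float)
            out = np.interp(z, xp, np.asarray(self.table, dtype=float), left=0.0, right=0.0)
            return out if out.shape else float(out)
        return self.at_distance(np.asarray(zone, dtype=float) - optimum)

    @property
    def breadth(self) -> int:
        """Largest distance (or zone offset) with a strictly positive value."""
        arr = np.asarray(self.table)
        nz = np.nonzero(arr > 0)[0]
        return int(nz[-1]) if nz.size else 0


# Calibrated default tables (configurable): narrow, near-maximal curves
# for the locally adapted genotypes; a broad, linearly declining curve for
# the standard plastic genotype (optimum 6).  The plastic table is the
# linear ramp ClimEff(d) = 1 - d/5: broader than any single locally
# adapted curve yet strictly below the locally adapted species' fitness
# envelope at every nonzero distance, so the locally adapted species
# keeps near-maximal fitness toward the range edges where the plastic
# one declines -- the premise distinguishing the two strategies.
LOCALLY_ADAPTED_CURVE = ResponseCurve((1.0, 0.75, 0.40, 0.10, 0.0))
PLASTIC_CURVE = ResponseCurve((1.0, 0.8, 0.6, 0.4, 0.2, 0.0))


def clim_eff(curve: ResponseCurve, optimum: float, zone) -> float | np.ndarray:
    """ClimEff multiplier for a genotype with ``optimum`` in climate ``zone``."""
    return curve.at_zone(optimum, zone)


def soften_curve(curve: ResponseCurve) -> ResponseCurve:
    """Halve every penalty: ClimEff'(d) = 1 - (1 - ClimEff(d)) / 2.

    Used to make the cumulative lifetime climate impact on a perennial
    resemble the single-year impact on an annual.
    """
    new = tuple(1.0 - (1.0 - v) / 2.0 for v in curve.table)
    return ResponseCurve(new, zone_indexed=curve.zone_indexed, zone_origin=curve.zone_origin)


def widely_plastic_curve(
    la_curves: list[tuple[float, ResponseCurve]],
    zone_min: int = 1,
    zone_max: int = 14,
) -> ResponseCurve:
    """Zone-indexed envelope: pointwise max of locally adapted curves.

    The widely plastic genotype's fitness at every zone equals the best
    locally adapted genotype's fitness there, so it combines broad
    tolerance with near-maximal fitness at the range edges.
    """
    if not la_curves:
        raise ValueError("need at least one locally adapted curve")
    zones = np.arange(zone_min, zone_max + 1, dtype=float)
    vals = np.max(
        [np.asarray(curve.at_zone(opt, zones)) for opt, curve in la_curves], axis=0
    )
    return ResponseCurve(tuple(vals.tolist()), zone_indexed=True, zone_origin=zone_min)
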