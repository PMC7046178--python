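"""Patch grid and time-dependent climate-zone field.

The landscape is a rectangular grid of square patches representing a slice
of a species' range along an elevation (or latitudinal) gradient.  Climate
varies only along the column axis: columns are grouped into contiguous
*climate bands*, each carrying one integer climate zone, warm at low column
indices and cold at high ones.  During the climate-shift phase the bands
move toward the cold end at an integer number of patch widths per year, so
new, warmer zones enter at the warm edge while the coldest zones disappear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandscapeSpec",
    "ClimateSchedule",
    "climate_at",
    "climate_columns",
    "zones_at_offset",
    "build_climate_grid",
    "landscape_variant",
    "LANDSCAPE_VARIANTS",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Geometry of the patch grid and the initial climate banding.

    Parameters
    ----------
    n_rows, n_cols
        Patch counts across the landscape width and along the gradient.
    patch_size
        Side length of a square patch in meters.
    band_width
        Number of columns per climate band.
    cold_band_multiplier
        Integer >= 1 widening only the coldest band (the extended
        landscape used to keep suitable climates from running off the
        cold edge); the extra columns extend the total landscape length.
    warmest_zone_initial, coldest_zone_initial
        Integer climate zones at the warm and cold ends at year 0.
    """

    n_rows: int = 50
    n_cols: int = 100
    patch_size: float = 20.0
    band_width: int = 10
    cold_band_multiplier: int = 1
    warmest_zone_initial: int = 10
    coldest_zone_initial: int = 1

    def __post_init__(self) -> None:
        n_zones = self.warmest_zone_initial - self.coldest_zone_initial + 1
        expected = self.band_width * n_zones + (self.cold_band_multiplier - 1) * self.band_width
        if expected != self.n_cols:
            raise ValueError(
                f"band layout covers {expected} columns but n_cols={self.n_cols}"
            )
        if self.cold_band_multiplier < 1:
            raise ValueError("cold_band_multiplier must be >= 1")

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class ClimateSchedule:
    """Timing and speed of the climate shift.

    The bands move ``patches_per_year`` columns toward the cold end each
    year for ``shift_duration`` years starting at ``shift_start_year``;
    before and after, the field is static.
    """

    shift_start_year: int = 0
    shift_duration: int = 20
    patches_per_year: int = 1

    def shift_offset(self, year: int) -> int:
        """Cumulative shift in patches at the *start* of ``year``."""
        elapsed = min(max(year - self.shift_start_year, 0), self.shift_duration)
        return self.patches_per_year * elapsed

    @property
    def total_zone_shift(self) -> float:
        return self.patches_per_year * self.shift_duration  # in patches


def _zone_of_offset(spec: LandscapeSpec, x: np.ndarray | int) -> np.ndarray | int:
    """Climate zone of effective column ``x`` on the unshifted banding.

    ``x`` may be negative (warmer zones that have entered from the warm
    edge).  The widened coldest band pins every column at or beyond the
    start of the cold band to the coldest zone.
    """
    x = np.asarray(x)
    band_idx = np.floor_divide(x, spec.band_width)
    zone = spec.warmest_zone_initial - band_idx
    n_ordinary = spec.warmest_zone_initial - spec.coldest_zone_initial  # bands before the cold one
    cold_start = n_ordinary * spec.band_width
    zone = np.where(x >= cold_start, spec.coldest_zone_initial, zone)
    if zone.shape == ():
        return int(zone)
    return zone.astype(np.int64)


def climate_at(
    spec: LandscapeSpec, schedule: ClimateSchedule, col: int, year: int
) -> int:
    """Climate zone of column ``col`` at the start of ``year``.

    Raises ``IndexError`` for a column outside the grid.
    """
    if not 0 <= col < spec.n_cols:
        raise IndexError(f"column {col} outside grid of {spec.n_cols} columns")
    if year < 0:
        raise ValueError("year must be >= 0")
    s = schedule.shift_offset(year)
    return int(_zone_of_offset(spec, col - s))


def zones_at_offset(spec: LandscapeSpec, shift_patches: int) -> np.ndarray:
    """Per-column climate zones after the bands have moved ``shift_patches``
    columns toward the cold end."""
    cols = np.arange(spec.n_cols, dtype=np.int64)
    return _zone_of_offset(spec, cols - shift_patches)


def climate_columns(
    spec: LandscapeSpec, schedule: ClimateSchedule, year: int
) -> np.ndarray:
    """Vector of climate zones per column (climate varies only by column)."""
    return zones_at_offset(spec, schedule.shift_offset(year))


def build_climate_grid(
    spec: LandscapeSpec, schedule: ClimateSchedule, year: int
) -> np.ndarray:
    """(n_rows, n_cols) integer grid of climate zones; all rows identical."""
    zones = climate_columns(spec, schedule, year)
    return np.broadcast_to(zones, (spec.n_rows, spec.n_cols)).copy()


# Named landscape/climate variants used by the scenario catalog.
LANDSCAPE_VARIANTS: dict[str, tuple[LandscapeSpec, ClimateSchedule]] = {
    # 1 km x 2 km, 200 m bands, shift one patch width (20 m) per year.
    "standard": (LandscapeSpec(), ClimateSchedule(patches_per_year=1)),
    # coldest band three times wider (landscape extended by 2 bands).
    "cold3x": (
        LandscapeSpec(n_cols=120, cold_band_multiplier=3),
        ClimateSchedule(patches_per_year=1),
    ),
    # doubled shift speed (40 m/yr) on the standard grid.
    "fast": (LandscapeSpec(), ClimateSchedule(patches_per_year=2)),
    # doubled speed on the extended grid: only the two coldest zones are lost.
    "fast_extended": (
        LandscapeSpec(n_cols=120, cold_band_multiplier=3),
        ClimateSchedule(patches_per_year=2),
    ),
    # 8 km shallow gradient: bands four times as wide, shift 80 m/yr so the
    # cold zones disappear at the same rate as on the standard landscape.
    "shallow8km": (
        LandscapeSpec(n_cols=400, band_width=40),
        ClimateSchedule(patches_per_year=4),
    ),
}


def landscape_variant(name: str) -> tuple[LandscapeSpec, ClimateSchedule]:
    """Look up a named landscape/climate variant (schedule has start year 0)."""
    try:
        return LANDSCAPE_VARIANTS[name]
    except KeyError:
        raise KeyError(
            f"unknown landscape variant {name!r}; known: {sorted(LANDSCAPE_VARIANTS)}"
        ) from None
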