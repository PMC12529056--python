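"""Survey preparation: rasterization, infestation accounting, masking.

The raw surveys are point records of sanitized green-attack trees (found and
destroyed by ground crews in year t) and red-top trees (killed in year t,
detected from the air in year t+1). Rasterized to the 1-km grid, they yield
the infestation variables

    I_t(x)  = m_t(x) + r_{t+1}(x)      total trees infested in year t
    I*_t(x) = I_t(x) - m_t(x) = r_{t+1}(x)   infested trees NOT sanitized,

where m_t is the sanitized count and r_{t+1} the red-top count attributed
back to year t. Only I* can seed next year's beetle pressure.

Model-fitting additionally masks the grid: pixels with pine volume below
1 m^3/km^2 are excluded (beetles landing there die), and the response data
are thinned to every third row and column to blunt residual spatial
autocorrelation. Pixels are classified by ancestry Q into jack (Q < 0.1),
hybrid (0.1 <= Q < 0.9) and lodgepole (Q >= 0.9); the model's L group is
{lodgepole, hybrid} under the default grouping chosen by cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import LandscapeGrid

__all__ = [
    "InfestationGrids",
    "AnalysisMask",
    "rasterize_surveys",
    "derive_infestation_vars",
    "build_analysis_mask",
    "classify_ancestry",
]

VOLUME_THRESHOLD = 1.0  # m^3/km^2
THIN_FACTOR = 3
JACK_CUT = 0.1
LODGEPOLE_CUT = 0.9

SPECIES_JACK, SPECIES_HYBRID, SPECIES_LODGEPOLE = 0, 1, 2


@dataclass
class InfestationGrids:
    """Per-year infestation rasters keyed by year.

    ``I[t] = m[t] + r[t+1]`` and ``I_star[t] = r[t+1]``; years with no
    following red-top survey cannot form I and are absent from I/I_star.
    """

    m: dict[int, np.ndarray]
    r: dict[int, np.ndarray]
    I: dict[int, np.ndarray] = field(default_factory=dict)
    I_star: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.I)


@dataclass
class AnalysisMask:
    """Pixel eligibility and species grouping for the likelihood."""

    volume_ok: np.ndarray
    thin_keep: np.ndarray
    species_class: np.ndarray
    group_L: np.ndarray
    group_J: np.ndarray

    @property
    def response_keep(self) -> np.ndarray:
        """Pixels entering the likelihood: habitat AND on the thinned lattice."""
        return self.volume_ok & self.thin_keep


def rasterize_surveys(
    points: pd.DataFrame, grid: LandscapeGrid
) -> tuple[dict[str, dict[int, np.ndarray]], pd.DataFrame]:
    """Accumulate survey points into per-year, per-kind count rasters.

    ``points`` needs columns year, x, y, count, kind (sanitized | red_top).
    Returns ``rasters[kind][year]`` plus a table of rejected out-of-grid
    points. Total mass is conserved: in-grid counts sum to the raster sums.
    """
    required = {"year", "x", "y", "count", "kind"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"points table missing columns: {sorted(missing)}")
    if len(points) and (points["count"] < 0).any():
        raise ValueError("negative counts in survey table")
    bad_kind = set(points["kind"].unique()) - {"sanitized", "red_top"} if len(points) else set()
    if bad_kind:
        raise ValueError(f"unknown survey kind(s): {sorted(bad_kind)}")

    rasters: dict[str, dict[int, np.ndarray]] = {"sanitized": {}, "red_top": {}}
    if not len(points):
        return rasters, points.iloc[0:0]

    row, col = grid.point_to_pixel(points["x"].to_numpy(), points["y"].to_numpy())
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    rejected = points.loc[~inside]
    pts = points.loc[inside]
    row, col = row[inside], col[inside]
    for (year, kind), idx in pts.groupby(["year", "kind"]).indices.items():
        arr = np.zeros(grid.shape, dtype=np.int64)
        np.add.at(arr, (row[idx], col[idx]), pts["count"].to_numpy()[idx])
        rasters[kind][int(year)] = arr
    return rasters, rejected


def derive_infestation_vars(
    m_rasters: dict[int, np.ndarray],
    r_rasters: dict[int, np.ndarray],
    years=None,
    shape: tuple[int, int] | None = None,
) -> InfestationGrids:
    """Combine sanitized and red-top rasters into I and I*.

    A year t enters I / I_star only when the year-(t+1) red-top raster
    exists (the final survey year has no forward red-top attribution).
    """
    if shape is None:
        for d in (m_rasters, r_rasters):
            if d:
                shape = next(iter(d.values())).shape
                break
    if shape is None:
        raise ValueError("cannot infer grid shape from empty rasters")
    if years is None:
        years = sorted(set(m_rasters) | {t - 1 for t in r_rasters})
    zeros = np.zeros(shape, dtype=np.int64)
    grids = InfestationGrids(m=dict(m_rasters), r=dict(r_rasters))
    for t in years:
        if t + 1 not in r_rasters:
            continue
        m_t = np.asarray(m_rasters.get(t, zeros))
        r_next = np.asarray(r_rasters[t + 1])
        if m_t.shape != shape or r_next.shape != shape:
            raise ValueError("raster shape mismatch across years")
        grids.I[t] = m_t + r_next
        grids.I_star[t] = r_next.copy()
    return grids


def classify_ancestry(
    Q: np.ndarray,
    jack_cut: float = JACK_CUT,
    lodgepole_cut: float = LODGEPOLE_CUT,
    hybrid_grouping: str = "lodgepole",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Classify pixels by ancestry and assign the model's L/J groups.

    Half-open boundaries: jack Q < jack_cut; hybrid jack_cut <= Q <
    lodgepole_cut; lodgepole Q >= lodgepole_cut. ``hybrid_grouping``
    ("lodgepole" | "jack") says which group absorbs the hybrid pixels; the
    default reflects the cross-validated choice.
    """
    Q = np.asarray(Q, dtype=float)
    if np.any((Q < 0) | (Q > 1)):
        raise ValueError("Q must lie in [0, 1]")
    if not 0 < jack_cut < lodgepole_cut <= 1:
        raise ValueError("require 0 < jack_cut < lodgepole_cut <= 1")
    if hybrid_grouping not in ("lodgepole", "jack"):
        raise ValueError("hybrid_grouping must be 'lodgepole' or 'jack'")
    species = np.full(Q.shape, SPECIES_HYBRID, dtype=np.int8)
    species[Q < jack_cut] = SPECIES_JACK
    species[Q >= lodgepole_cut] = SPECIES_LODGEPOLE
    if hybrid_grouping == "lodgepole":
        group_L = species != SPECIES_JACK
    else:
        group_L = species == SPECIES_LODGEPOLE
    return species, group_L, ~group_L


def build_analysis_mask(
    landscape: LandscapeGrid,
    volume_threshold: float = VOLUME_THRESHOLD,
    thin_factor: int = THIN_FACTOR,
    thin_offset: int = 0,
    hybrid_grouping: str = "lodgepole",
) -> AnalysisMask:
    """Build the pixel-eligibility mask and species grouping.

    thin_keep selects the intersection of every ``thin_factor``-th row and
    column starting at ``thin_offset``; group membership is defined on
    habitat (volume_ok) pixels.
    """
    if thin_factor < 1:
        raise ValueError("thin_factor must be >= 1")
    if not 0 <= thin_offset < thin_factor:
        raise ValueError("thin_offset must lie in [0, thin_factor)")
    if volume_threshold < 0:
        raise ValueError("volume_threshold must be >= 0")
    volume_ok = landscape.volume >= volume_threshold
    rows = (np.arange(landscape.n_rows) - thin_offset) % thin_factor == 0
    cols = (np.arange(landscape.n_cols) - thin_offset) % thin_factor == 0
    thin_keep = rows[:, None] & cols[None, :]
    species, group_L, group_J = classify_ancestry(
        landscape.Q, hybrid_grouping=hybrid_grouping
    )
    return AnalysisMask(
        volume_ok=volume_ok,
        thin_keep=thin_keep,
        species_class=species,
        group_L=group_L & volume_ok,
        group_J=group_J & volume_ok,
    )
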