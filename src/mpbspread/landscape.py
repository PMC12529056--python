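"""Landscape rasters and synthetic landscape generation.

A :class:`LandscapeGrid` bundles the co-registered 1-km rasters the analysis
needs — pine volume (m^3/km^2), pine ancestry Q (0 = pure jack pine, 1 = pure
lodgepole pine), and winter survival theta in [0, 1] — together with the
geometry used to measure spread: a polygon of consistently surveyed area and
a directed west-to-east projection line.

The synthetic generator emulates the west Alberta -> east Alberta transition:
lodgepole pine in the west, a hybrid band in the middle, jack pine in the
east, lognormal pine volumes per species, and a logit-normal winter-survival
field. Coordinates are km on a local planar grid; pixel (i, j) has its
center at (x, y) = ((j + 0.5) * pixel_size, (i + 0.5) * pixel_size), with x
increasing eastward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit
from shapely.geometry import LineString, Polygon, box, mapping, shape

__all__ = ["GradientSpec", "LandscapeGrid", "generate_landscape"]


@dataclass(frozen=True)
class GradientSpec:
    """Parameters of the synthetic west->east ancestry/volume gradient.

    ``q_west``/``q_east`` are the expected Q at the west/east edges;
    ``band_width`` (km) controls how gradually Q transitions (0 gives a hard
    step at the domain midline). Volumes are lognormal per species with
    (mean, sd) of log volume; the west (lodgepole) forest is denser. theta
    is a logit-normal field with the given logit-scale mean and sd.
    """

    q_west: float = 1.0
    q_east: float = 0.0
    band_width: float = 20.0
    q_noise_sd: float = 0.04
    log_volume_mean_lodgepole: float = np.log(2000.0)
    log_volume_sd_lodgepole: float = 0.6
    log_volume_mean_jack: float = np.log(700.0)
    log_volume_sd_jack: float = 0.7
    bare_fraction: float = 0.05
    theta_logit_mean: float = 0.0
    theta_logit_sd: float = 0.8

    def __post_init__(self):
        for q in (self.q_west, self.q_east):
            if not 0.0 <= q <= 1.0:
                raise ValueError("gradient Q endpoints must lie in [0, 1]")
        if self.band_width < 0:
            raise ValueError("band_width must be >= 0")


@dataclass
class LandscapeGrid:
    """Co-registered rasters plus spread-measurement geometry."""

    volume: np.ndarray
    Q: np.ndarray
    theta: np.ndarray
    pixel_size: float = 1.0
    spread_polygon: Polygon | None = None
    projection_line: LineString | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not (self.volume.shape == self.Q.shape == self.theta.shape):
            raise ValueError("volume, Q and theta must share a shape")
        if np.any(self.volume < 0):
            raise ValueError("volume must be >= 0")
        if np.any((self.Q < 0) | (self.Q > 1)):
            raise ValueError("Q must lie in [0, 1]")
        if np.any((self.theta < 0) | (self.theta > 1)):
            raise ValueError("theta must lie in [0, 1]")
        if self.projection_line is not None:
            if self.projection_line.length <= 0:
                raise ValueError("projection_line must have nonzero length")
            if not box(*self.bounds).contains(self.projection_line):
                raise ValueError("projection_line must lie inside the raster bounds")

    @property
    def n_rows(self) -> int:
        return self.volume.shape[0]

    @property
    def n_cols(self) -> int:
        return self.volume.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.volume.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.pixel_size, y0 + self.n_rows * self.pixel_size)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate rasters in km."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def point_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) via the half-open cell convention."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.pixel_size).astype(int)
        row = np.floor((np.asarray(y) - y0) / self.pixel_size).astype(int)
        return row, col

    # ---- I/O ------------------------------------------------------------

    def save(self, directory) -> None:
        """Write rasters as TIFF and geometry as GeoJSON into a directory."""
        import tifffile

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        grid_meta = {"pixel_size": self.pixel_size, "origin": list(self.origin)}
        for name, arr in [("volume", self.volume), ("Q", self.Q), ("theta", self.theta)]:
            tifffile.imwrite(
                directory / f"{name}.tif",
                arr.astype(np.float32),
                description=json.dumps(grid_meta),
            )
        features = []
        if self.spread_polygon is not None:
            features.append(
                {"type": "Feature", "properties": {"role": "spread_polygon"},
                 "geometry": mapping(self.spread_polygon)}
            )
        if self.projection_line is not None:
            features.append(
                {"type": "Feature", "properties": {"role": "projection_line"},
                 "geometry": mapping(self.projection_line)}
            )
        (directory / "geometry.geojson").write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def load(cls, directory) -> "LandscapeGrid":
        import tifffile

        directory = Path(directory)
        arrays, meta = {}, {"pixel_size": 1.0, "origin": [0.0, 0.0]}
        for name in ("volume", "Q", "theta"):
            with tifffile.TiffFile(directory / f"{name}.tif") as tf:
                arrays[name] = tf.asarray().astype(float)
                desc = tf.pages[0].tags.get("ImageDescription")
                if desc is not None:
                    try:
                        meta.update(json.loads(desc.value))
                    except (ValueError, TypeError):
                        pass
        polygon = line = None
        geom_path = directory / "geometry.geojson"
        if geom_path.exists():
            fc = json.loads(geom_path.read_text())
            for feat in fc.get("features", []):
                geom = shape(feat["geometry"])
                role = feat.get("properties", {}).get("role")
                if role == "spread_polygon":
                    polygon = geom
                elif role == "projection_line":
                    line = geom
        return cls(
            volume=arrays["volume"], Q=arrays["Q"], theta=arrays["theta"],
            pixel_size=float(meta["pixel_size"]), origin=tuple(meta["origin"]),
            spread_polygon=polygon, projection_line=line,
        )


def generate_landscape(
    n_rows: int,
    n_cols: int,
    seed: int,
    gradient_spec: GradientSpec = GradientSpec(),
    pixel_size: float = 1.0,
) -> LandscapeGrid:
    """Generate a synthetic west->east lodgepole -> hybrid -> jack landscape.

    Q decreases (in expectation) from ``q_west`` to ``q_east`` along columns
    following a logistic ramp of width ``band_width`` centered on the domain
    midline, with truncated Gaussian pixel noise. Volume is lognormal with
    species-dependent parameters (interpolated through the hybrid zone) and
    a ``bare_fraction`` of near-zero-volume pixels; theta is logit-normal.

    The spread polygon is the full raster extent inset by one pixel, and the
    projection line runs west to east through the domain's vertical middle.
    Deterministic: the same seed gives bit-identical output.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("n_rows and n_cols must be >= 8")
    g = gradient_spec
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A5D]))

    x_center = (np.arange(n_cols) + 0.5) * pixel_size
    mid = n_cols * pixel_size / 2.0
    if g.band_width > 0:
        ramp = expit(-(x_center - mid) / (g.band_width / 8.0))  # ~[0,1], west high
    else:
        ramp = (x_center < mid).astype(float)
    q_profile = g.q_east + (g.q_west - g.q_east) * ramp
    Q = np.clip(q_profile[None, :] + rng.normal(0.0, g.q_noise_sd, (n_rows, n_cols)), 0.0, 1.0)
    if g.band_width == 0:  # keep the degenerate case an exact two-level step
        Q = np.broadcast_to(q_profile, (n_rows, n_cols)).copy()

    # volume: lognormal with parameters blended by the expected ancestry ramp
    w = ramp[None, :]
    log_mu = g.log_volume_mean_jack + (g.log_volume_mean_lodgepole - g.log_volume_mean_jack) * w
    log_sd = g.log_volume_sd_jack + (g.log_volume_sd_lodgepole - g.log_volume_sd_jack) * w
    volume = rng.lognormal(mean=np.broadcast_to(log_mu, (n_rows, n_cols)),
                           sigma=np.broadcast_to(log_sd, (n_rows, n_cols)))
    bare = rng.random((n_rows, n_cols)) < g.bare_fraction
    volume = np.where(bare, rng.uniform(0.0, 0.5, (n_rows, n_cols)), volume)

    theta = expit(rng.normal(g.theta_logit_mean, g.theta_logit_sd, (n_rows, n_cols)))

    width, height = n_cols * pixel_size, n_rows * pixel_size
    polygon = box(pixel_size, pixel_size, width - pixel_size, height - pixel_size)
    line = LineString([(pixel_size, height / 2.0), (width - pixel_size, height / 2.0)])
    return LandscapeGrid(
        volume=volume, Q=Q, theta=theta, pixel_size=pixel_size,
        spread_polygon=polygon, projection_line=line,
        meta={"seed": int(seed), "gradient_spec": g.__dict__.copy()},
    )
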