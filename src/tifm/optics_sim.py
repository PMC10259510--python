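"""Synthetic time-lapse rendering of the probe tip/foil in tissue.

Frames are rendered with analytically anti-aliased tip profiles so the
intensity-weighted centroid of the noise-free, blur-free profile sits at the
ground-truth tip position by construction. Imaging through tissue is modeled
as a Gaussian blur whose s.d. grows linearly with the imaging depth D_I,
plus a static background texture, Gaussian read noise and Poisson-scaled
shot noise. Ground truth travels with every frame, so the vision module can
be scored against it.

Pixel convention: pixel column ``j`` spans x ∈ [j·p, (j+1)·p) µm where p is
the pixel size; its center is at (j + 0.5)·p. ``um_to_px``/``px_to_um``
convert between µm positions and fractional pixel-center coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from tifm.plant_twin import PlantState, ProbeSpec


@dataclass(frozen=True)
class OpticsConfig:
    """Camera + imaging-path parameters.

    pixel_size µm/px and frame_rate_max fps reflect the hardware bound of
    roughly 0.5 µm pixels at up to ~200 frames/s. ``blur_scale`` is the
    Gaussian blur s.d. in px added per 100 µm of imaging depth D_I; the
    contrast loss with depth is not quantified by any measurement here, so it
    is a free fixture parameter.
    """

    pixel_size: float = 0.5
    frame_rate_max: float = 200.0
    field_of_view: tuple[int, int] = (96, 192)  # (rows, cols) px
    imaging_depth: float = 20.0  # D_I, µm
    blur_scale: float = 1.5  # px of Gaussian s.d. per 100 µm of D_I
    background_level: float = 12000.0  # grey levels (16-bit)
    background_texture_amplitude: float = 150.0
    read_noise: float = 20.0  # grey levels s.d.
    shot_noise_scale: float = 0.3  # s.d. = scale·√intensity
    tip_contrast: float = 8000.0  # grey levels
    channel: str = "brightfield"  # "brightfield" | "fluorescent"
    texture_seed: int = 1234  # static dish/tissue texture
    density_contrast: float = 0.0  # grey levels per unit linear density

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.blur_scale < 0:
            raise ValueError("blur_scale must be ≥ 0")
        if self.channel not in ("brightfield", "fluorescent"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def blur_sigma_px(self) -> float:
        return self.blur_scale * self.imaging_depth / 100.0

    def um_to_px(self, x_um: float) -> float:
        return x_um / self.pixel_size - 0.5

    def px_to_um(self, x_px: float) -> float:
        return (x_px + 0.5) * self.pixel_size


@dataclass
class Frame:
    pixels: np.ndarray  # 2-D uint16
    time_s: float
    true_tip_um: float
    pixel_size: float
    channel: str
    out_of_view: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class Movie:
    frames: np.ndarray  # (n, rows, cols) uint16
    times_s: np.ndarray
    true_tip_um: np.ndarray
    optics: OpticsConfig
    probe: ProbeSpec

    def __len__(self) -> int:
        return len(self.times_s)

    def frame(self, i: int) -> Frame:
        return Frame(
            pixels=self.frames[i],
            time_s=float(self.times_s[i]),
            true_tip_um=float(self.true_tip_um[i]),
            pixel_size=self.optics.pixel_size,
            channel=self.optics.channel,
        )


# --------------------------------------------------------------------------
# profile rendering
# --------------------------------------------------------------------------


def _x_interval_coverage(nx: int, xl: np.ndarray, xr: np.ndarray) -> np.ndarray:
    """Per-row coverage of pixel columns by x-intervals [xl, xr] (px units).

    Rows with xr <= xl contribute nothing. Returns (rows, nx) float array of
    the covered fraction of each pixel.
    """
    cols = np.arange(nx)
    lo = np.maximum(xl[:, None], cols[None, :])
    hi = np.minimum(xr[:, None], cols[None, :] + 1.0)
    return np.clip(hi - lo, 0.0, 1.0)


def _tip_profile(probe: ProbeSpec, optics: OpticsConfig, x_tip_um: float,
                 shape_rc: tuple[int, int]) -> np.ndarray:
    """Anti-aliased occupancy map of the tip/foil, centroid at the tip.

    Shapes (plan view, 1-D measurement axis = x/columns):

    * foil: rectangle foil_thickness (x) × foil_width (y), centered at X_T;
    * sharp/triangular: filled triangle of base ``tip_width`` (y) extending
      ``tip_extent`` along x, shifted so its area centroid is at X_T;
    * fluorescent label: Gaussian spot (handled in render_frame).

    Sub-row supersampling (8×) keeps y-edge coverage smooth; x coverage is
    exact per sub-row, so the x-centroid of the map equals X_T to well below
    0.01 px.
    """
    ny, nx = shape_rc
    sub = 8
    yc = ny / 2.0  # shape centered vertically (px, edge coordinates)
    x_tip_px = x_tip_um / optics.pixel_size  # edge coordinate of the centroid
    y_sub = (np.arange(ny * sub) + 0.5) / sub  # sub-row centers (px)

    if probe.tip_shape == "foil":
        half_x = 0.5 * probe.foil_thickness / optics.pixel_size
        half_y = 0.5 * probe.foil_width / optics.pixel_size
        inside = np.abs(y_sub - yc) <= half_y
        xl = np.where(inside, x_tip_px - half_x, 0.0)
        xr = np.where(inside, x_tip_px + half_x, 0.0)
    else:
        # triangle: base at x0, apex at x0 + extent; centroid at x0 + extent/3
        extent = max(probe.tip_width, 4.0 * optics.pixel_size) / optics.pixel_size
        half_y = 0.5 * probe.tip_width / optics.pixel_size
        x0 = x_tip_px - extent / 3.0
        frac = 1.0 - np.abs(y_sub - yc) / half_y  # 1 at midline, 0 at base edges
        inside = frac > 0
        xl = np.where(inside, x0, 0.0)
        xr = np.where(inside, x0 + extent * np.clip(frac, 0.0, 1.0), 0.0)

    cov_sub = _x_interval_coverage(nx, xl, xr)
    return cov_sub.reshape(ny, sub, nx).mean(axis=1)


def _background(optics: OpticsConfig, shape_rc: tuple[int, int]) -> np.ndarray:
    """Static textured background, deterministic per (texture_seed, shape)."""
    rng = np.random.default_rng(optics.texture_seed)
    tex = rng.normal(0.0, 1.0, shape_rc)
    tex = gaussian_filter(tex, 3.0)
    tex *= optics.background_texture_amplitude / max(tex.std(), 1e-12)
    base = 0.05 * optics.background_level if optics.channel == "fluorescent" \
        else optics.background_level
    return base + tex


def render_frame(
    state: PlantState | float,
    probe: ProbeSpec,
    optics: OpticsConfig,
    rng: np.random.Generator | int | None = None,
    time_s: float | None = None,
) -> Frame:
    """Render one frame of the tip/foil at its ground-truth position.

    ``state`` may be a full PlantState or a bare tip position in µm. The tip
    is dark on bright background (brightfield) or a bright Gaussian spot
    (fluorescent channel). Out-of-view tips render background only and set
    the ``out_of_view`` flag.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if isinstance(state, PlantState):
        x_tip = state.X_T_true
        t = state.time if time_s is None else time_s
        density = state.cell_density
        grid = state.density_grid
    else:
        x_tip = float(state)
        t = 0.0 if time_s is None else time_s
        density, grid = None, None

    ny, nx = optics.field_of_view
    img = _background(optics, (ny, nx)).copy()

    fov_max_um = nx * optics.pixel_size
    out_of_view = not (0.0 <= x_tip < fov_max_um)

    if density is not None and grid is not None and optics.density_contrast > 0:
        x_centers = (np.arange(nx) + 0.5) * optics.pixel_size
        dens = np.interp(x_centers, grid, density, left=0.0, right=0.0)
        img += optics.density_contrast * dens[None, :]

    if not out_of_view:
        if optics.channel == "fluorescent":
            x_px = optics.um_to_px(x_tip)
            cols = np.arange(nx)
            rows = np.arange(ny)
            s = max(probe.tip_width / optics.pixel_size / 4.0, 1.0)
            spot = np.exp(-0.5 * ((cols[None, :] - x_px) ** 2
                                  + (rows[:, None] - (ny - 1) / 2.0) ** 2) / s**2)
            img += optics.tip_contrast * spot
        else:
            cov = _tip_profile(probe, optics, x_tip, (ny, nx))
            img -= optics.tip_contrast * cov

    if optics.blur_sigma_px > 0:
        img = gaussian_filter(img, optics.blur_sigma_px)

    if rng is not None:
        if optics.shot_noise_scale > 0:
            img = img + rng.normal(0.0, 1.0, img.shape) * (
                optics.shot_noise_scale * np.sqrt(np.clip(img, 0.0, None))
            )
        if optics.read_noise > 0:
            img = img + rng.normal(0.0, optics.read_noise, img.shape)

    pixels = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return Frame(
        pixels=pixels,
        time_s=t,
        true_tip_um=x_tip,
        pixel_size=optics.pixel_size,
        channel=optics.channel,
        out_of_view=out_of_view,
        meta={"blur_sigma_px": optics.blur_sigma_px},
    )


def render_movie(
    trajectory: pd.DataFrame,
    probe: ProbeSpec,
    optics: OpticsConfig,
    sampling_interval: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> Movie:
    """Render one frame per trajectory sample (columns time_s, X_T_true_um).

    ``sampling_interval`` subsamples the trajectory to at most one frame per
    interval; it must respect the camera's maximum frame rate. Frame
    timestamps equal the trajectory times exactly (no resampling drift).
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    t = trajectory["time_s"].to_numpy(dtype=float)
    x = trajectory["X_T_true_um"].to_numpy(dtype=float)
    if sampling_interval is not None:
        if sampling_interval < 1.0 / optics.frame_rate_max:
            raise ValueError("sampling_interval exceeds the camera frame rate")
        keep = [0]
        for i in range(1, len(t)):
            if t[i] - t[keep[-1]] >= sampling_interval - 1e-9:
                keep.append(i)
        t, x = t[keep], x[keep]
    frames = np.empty((len(t), *optics.field_of_view), dtype=np.uint16)
    for i in range(len(t)):
        frames[i] = render_frame(x[i], probe, optics, rng, time_s=t[i]).pixels
    return Movie(frames=frames, times_s=t, true_tip_um=x, optics=optics, probe=probe)


# --------------------------------------------------------------------------
# I/O: multi-page 16-bit TIFF + sidecar ground truth + JSON metadata
# --------------------------------------------------------------------------


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a TIFF stack with sidecar ground-truth CSV and JSON metadata."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames, photometric="minisblack")
    pd.DataFrame(
        {"time_s": movie.times_s, "X_T_true_um": movie.true_tip_um}
    ).to_csv(path.with_suffix(".truth.csv"), index=False)
    meta = {
        "pixel_size_um": movie.optics.pixel_size,
        "channel": movie.optics.channel,
        "imaging_depth_um": movie.optics.imaging_depth,
        "n_frames": int(len(movie)),
        "probe": asdict(movie.probe),
        "optics": asdict(movie.optics),
    }
    meta["optics"]["field_of_view"] = list(movie.optics.field_of_view)
    meta["probe"]["spring_constant"] = movie.probe.spring_constant
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_movie(path: str | Path) -> Movie:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    truth = pd.read_csv(path.with_suffix(".truth.csv"))
    opt_kwargs = dict(meta["optics"])
    opt_kwargs["field_of_view"] = tuple(opt_kwargs["field_of_view"])
    optics = OpticsConfig(**opt_kwargs)
    probe = ProbeSpec(**meta["probe"])
    return Movie(
        frames=frames,
        times_s=truth["time_s"].to_numpy(),
        true_tip_um=truth["X_T_true_um"].to_numpy(),
        optics=optics,
        probe=probe,
    )
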