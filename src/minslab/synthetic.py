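"""Ground-truth movie generator for testing the image pipeline.

Generates calibrated single- and dual-plane movie stacks with the wave
classes the analysis must recognize (traveling, standing, homogeneous,
phase-wave), plus the imaging artifacts the correction stage removes:
exponential photobleaching (~20% decay over a movie), illumination
vignetting, static fluorescent specks, and shot/read noise.  All outputs
are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .patterns import MovieStack, AnalysisError


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class WaveSpec:
    """Specification of a clean wave movie."""

    wave_class: str  # 'traveling' | 'standing' | 'homogeneous' | 'phase_wave'
    wavelength: float = 50.0  # μm (ignored for homogeneous)
    period: float = 120.0  # s
    amplitude: float = 40.0
    offset: float = 100.0
    direction: float = 0.0  # rad, propagation / wave-vector direction
    phase_gradient: float = 0.0  # rad/μm, phase_wave only
    shape: tuple[int, int] = (128, 128)  # (rows, cols) px
    pixel_size: float = 1.0  # μm
    frame_interval: float = 30.0  # s
    duration: float = 1800.0  # s
    seed: int = 0

    def __post_init__(self):
        if self.wave_class not in ("traveling", "standing", "homogeneous", "phase_wave"):
            raise SyntheticError(f"unknown wave class {self.wave_class!r}")
        if not (self.offset >= self.amplitude >= 0):
            raise SyntheticError("need offset >= amplitude >= 0 for nonnegative intensities")
        if self.period <= 2 * self.frame_interval:
            raise SyntheticError("period must exceed twice the frame interval")
        if self.wave_class != "homogeneous" and self.wavelength <= 2 * self.pixel_size:
            raise SyntheticError("wavelength must exceed twice the pixel size")


@dataclass(frozen=True)
class ArtifactSpec:
    """Imaging artifacts applied on top of a clean stack."""

    bleach_fraction: float = 0.2  # total intensity decay over the movie
    vignette_strength: float = 0.3  # 0 = flat illumination
    vignette_width: float = 0.8  # Gaussian width in units of half the image size
    speck_count: int = 30
    speck_intensity: float = 60.0
    speck_size: float = 1.5  # px, Gaussian radius
    noise_model: str = "gaussian"  # 'gaussian' | 'poisson' | 'none'
    noise_sigma: float = 1.0  # gaussian std
    poisson_scale: float = 1.0  # counts per intensity unit
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.bleach_fraction < 1):
            raise SyntheticError("bleach_fraction must be in [0, 1)")
        for name in ("vignette_strength", "speck_intensity", "noise_sigma", "poisson_scale"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be >= 0")
        if self.noise_model not in ("gaussian", "poisson", "none"):
            raise SyntheticError(f"unknown noise model {self.noise_model!r}")

    @classmethod
    def none(cls) -> "ArtifactSpec":
        return cls(bleach_fraction=0.0, vignette_strength=0.0, speck_count=0,
                   noise_model="none", noise_sigma=0.0)


def gen_stack(spec: WaveSpec) -> MovieStack:
    """Render the clean wave movie for a spec (deterministic given the seed)."""
    ny, nx = spec.shape
    y = (np.arange(ny) + 0.5) * spec.pixel_size
    x = (np.arange(nx) + 0.5) * spec.pixel_size
    Y, X = np.meshgrid(y, x, indexing="ij")
    u = np.cos(spec.direction) * X + np.sin(spec.direction) * Y
    t = np.arange(int(round(spec.duration / spec.frame_interval)) + 1) * spec.frame_interval
    if len(t) < 2:
        raise SyntheticError("duration shorter than one frame interval")
    omega = 2 * np.pi / spec.period
    k = 2 * np.pi / spec.wavelength
    frames = np.empty((len(t), ny, nx))
    for i, ti in enumerate(t):
        if spec.wave_class == "traveling":
            frames[i] = spec.offset + spec.amplitude * np.sin(k * u - omega * ti)
        elif spec.wave_class == "standing":
            frames[i] = spec.offset + spec.amplitude * np.sin(k * u) * np.cos(omega * ti)
        elif spec.wave_class == "homogeneous":
            frames[i] = spec.offset + spec.amplitude * np.cos(omega * ti)
        else:  # phase_wave
            frames[i] = spec.offset + spec.amplitude * np.cos(omega * ti - spec.phase_gradient * u)
    return MovieStack(data=frames, pixel_size=spec.pixel_size,
                      frame_interval=spec.frame_interval)


def _speck_image(shape: tuple[int, int], art: ArtifactSpec, rng) -> np.ndarray:
    ny, nx = shape
    img = np.zeros((ny, nx))
    if art.speck_count == 0 or art.speck_intensity == 0:
        return img
    ys = rng.uniform(0, ny, art.speck_count)
    xs = rng.uniform(0, nx, art.speck_count)
    amp = rng.uniform(0.5, 1.0, art.speck_count) * art.speck_intensity
    yy = np.arange(ny)[:, None]
    xx = np.arange(nx)[None, :]
    for cy, cx, a in zip(ys, xs, amp):
        img += a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * art.speck_size**2))
    return img


def _vignette(shape: tuple[int, int], art: ArtifactSpec) -> np.ndarray:
    ny, nx = shape
    if art.vignette_strength == 0:
        return np.ones((ny, nx))
    y = (np.arange(ny) - (ny - 1) / 2) / (ny / 2)
    x = (np.arange(nx) - (nx - 1) / 2) / (nx / 2)
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    g = np.exp(-r2 / (2 * art.vignette_width**2))
    return (1 - art.vignette_strength) + art.vignette_strength * g


def add_artifacts(stack: MovieStack, art: ArtifactSpec) -> MovieStack:
    """Apply bleach × vignette, add the static speck image, then noise.

    Negative intensities produced by noise are clipped at zero (the clip
    count is stored in the returned stack's ``channel`` note only when
    nonzero clips occur; callers keep the clean stack as ground truth).
    """
    rng = np.random.default_rng(art.seed)
    nt = stack.n_frames
    shape = stack.data.shape[1:]
    if art.bleach_fraction > 0 and nt > 1:
        rate = -np.log(1 - art.bleach_fraction) / (nt - 1)
        bleach = np.exp(-rate * np.arange(nt))
    else:
        bleach = np.ones(nt)
    vign = _vignette(shape, art)
    out = stack.data * bleach[:, None, None] * vign[None]
    out = out + _speck_image(shape, art, rng)[None]
    if art.noise_model == "gaussian" and art.noise_sigma > 0:
        out = out + rng.normal(0, art.noise_sigma, out.shape)
    elif art.noise_model == "poisson" and art.poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0) * art.poisson_scale) / art.poisson_scale
    n_neg = int((out < 0).sum())
    if n_neg:
        out = np.maximum(out, 0.0)
    result = stack.copy_with(out)
    result.channel = (stack.channel + f"|clipped:{n_neg}") if n_neg else stack.channel
    return result


def gen_pair(
    spec: WaveSpec,
    phase_shift: float = 0.0,
    decorrelate: float = 0.0,
    seed: int = 0,
    cell_size: float = 10.0,
) -> tuple[MovieStack, MovieStack]:
    """Dual-plane pair: bottom = top with a temporal phase shift; in a random
    decorrelate-fraction of cell_size × cell_size μm² cells the bottom is
    replaced by an independently seeded pattern (random direction and an
    incommensurate frequency, so its traces decorrelate from the top)."""
    if not (0 <= phase_shift < 2 * np.pi):
        raise SyntheticError("phase_shift must lie in [0, 2π)")
    if not (0 <= decorrelate <= 1):
        raise SyntheticError("decorrelate must lie in [0, 1]")
    top = gen_stack(spec)
    shifted_spec = spec
    # temporal phase shift: regenerate with time origin shifted
    t_shift = phase_shift / (2 * np.pi) * spec.period
    bottom = _gen_stack_shifted(spec, t_shift)
    if decorrelate > 0:
        rng = np.random.default_rng(seed)
        ny, nx = spec.shape
        n_px = max(1, int(round(cell_size / spec.pixel_size)))
        ncy, ncx = ny // n_px, nx // n_px
        pick = rng.random((ncy, ncx)) < decorrelate
        for iy in range(ncy):
            for ix in range(ncx):
                if not pick[iy, ix]:
                    continue
                cell_rng = np.random.default_rng((seed + 1, iy, ix))
                alt = replace(
                    spec,
                    direction=cell_rng.uniform(0, 2 * np.pi),
                    period=spec.period / cell_rng.uniform(1.4, 1.7),
                    seed=int(cell_rng.integers(0, 2**31 - 1)),
                )
                patch = _gen_stack_shifted(alt, cell_rng.uniform(0, spec.period))
                sl = (slice(None), slice(iy * n_px, (iy + 1) * n_px),
                      slice(ix * n_px, (ix + 1) * n_px))
                bottom.data[sl] = patch.data[sl]
    top.plane, bottom.plane = "top", "bottom"
    return top, bottom


def _gen_stack_shifted(spec: WaveSpec, t_shift: float) -> MovieStack:
    ny, nx = spec.shape
    y = (np.arange(ny) + 0.5) * spec.pixel_size
    x = (np.arange(nx) + 0.5) * spec.pixel_size
    Y, X = np.meshgrid(y, x, indexing="ij")
    u = np.cos(spec.direction) * X + np.sin(spec.direction) * Y
    t = np.arange(int(round(spec.duration / spec.frame_interval)) + 1) * spec.frame_interval
    omega = 2 * np.pi / spec.period
    k = 2 * np.pi / spec.wavelength
    frames = np.empty((len(t), ny, nx))
    for i, ti in enumerate(t + t_shift):
        if spec.wave_class == "traveling":
            frames[i] = spec.offset + spec.amplitude * np.sin(k * u - omega * ti)
        elif spec.wave_class == "standing":
            frames[i] = spec.offset + spec.amplitude * np.sin(k * u) * np.cos(omega * ti)
        elif spec.wave_class == "homogeneous":
            frames[i] = spec.offset + spec.amplitude * np.cos(omega * ti)
        else:
            frames[i] = spec.offset + spec.amplitude * np.cos(omega * ti - spec.phase_gradient * u)
    return MovieStack(data=frames, pixel_size=spec.pixel_size,
                      frame_interval=spec.frame_interval)
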