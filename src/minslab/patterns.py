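"""Image-sequence analysis: artifact correction, pattern length/time scales,
dual-plane correlation, and operational pattern classification.

The pipeline mirrors standard dual-plane TIRF/confocal practice for Min
pattern movies:

* bleach correction by per-frame mean normalization (≲20% decay over long
  movies), static-background subtraction and flat-field division
  (``corrected = (movie − static)/illumination``);
* dominant wavelength from the first side maximum of each frame's spatial
  autocorrelation sampled along the dominant pattern orientation; dominant
  period from temporal autocorrelation of kymographs;
* membrane-to-membrane synchronization from per-subregion (≈10×10 μm²)
  Pearson correlation between top and bottom time traces, classified with
  thresholds +0.7 (correlated) and −0.3 (anticorrelated);
* pattern-class labelling from the space-time spectrum: the dominant
  (wavenumber, frequency) line and the windowed left/right propagation
  asymmetry separate homogeneous oscillations (including phase waves),
  standing waves, and traveling waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MovieStack", "CorrelationReport", "PatternLabel", "AnalysisError",
    "correct_stack", "spatial_wavelength", "temporal_period",
    "topbottom_correlation", "classify_correlation", "classify_pattern",
    "classify_pattern_kymo",
]


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class MovieStack:
    """Calibrated image time series: data shape (frames, rows, cols)."""

    data: np.ndarray
    pixel_size: float  # μm
    frame_interval: float  # s
    plane: str = "single"  # 'top' | 'bottom' | 'single'
    channel: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise AnalysisError(f"stack must be 3D (t, y, x), got {self.data.shape}")
        if not (self.pixel_size > 0 and self.frame_interval > 0):
            raise AnalysisError("pixel size and frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    def copy_with(self, data: np.ndarray) -> "MovieStack":
        return MovieStack(data=data, pixel_size=self.pixel_size,
                          frame_interval=self.frame_interval,
                          plane=self.plane, channel=self.channel)


@dataclass
class CorrelationReport:
    """Per-subregion top-bottom temporal correlations and their
    classification into correlated / anticorrelated / neither fractions."""

    cell_size: float  # μm
    cell_centers_x: np.ndarray  # μm
    cell_centers_y: np.ndarray
    correlations: np.ndarray  # (ny_cells, nx_cells), NaN = undefined
    thresholds: tuple[float, float]
    fractions: dict  # {'correlated','anticorrelated','neither'}
    histogram: tuple[np.ndarray, np.ndarray]  # counts, bin edges
    n_undefined: int = 0
    window: tuple[float, float] | None = None

    @property
    def values(self) -> np.ndarray:
        v = self.correlations.ravel()
        return v[~np.isnan(v)]


@dataclass
class PatternLabel:
    """Operational pattern class with its supporting metrics."""

    pattern_class: str  # traveling_wave | standing_wave | homogeneous_oscillation | indeterminate
    frequency: float | None = None  # Hz
    period: float | None = None  # s
    phase_spread: float | None = None  # 1 - |R1|
    phase_doubling_spread: float | None = None  # 1 - |R2|
    grad_mean: float | None = None  # rad/μm
    grad_cv: float | None = None
    reason: str = ""


# ---------------------------------------------------------------------------
# Correction pipeline
# ---------------------------------------------------------------------------

def correct_stack(
    stack: MovieStack,
    illum_sigma_frac: float = 0.25,
    static_sigma_px: float = 4.0,
    illum_floor: float = 0.05,
) -> MovieStack:
    """Bleach, static-background, and illumination correction.

    1. Each frame is normalized by its mean intensity (then rescaled by the
       first-frame mean so the intensity scale is preserved), removing slow
       photobleaching.
    2. The static background (specks, scratches) is the temporal median of
       the normalized movie minus its own smooth baseline — moving wave
       features average out under the median; removing the baseline keeps
       only the small-scale static features, leaving the smooth illumination
       structure to step 3.
    3. The illumination field is the strongly smoothed, static-subtracted
       frame average, normalized to max 1; the correction is
       (frame − static)/illumination.
    """
    if stack.n_frames < 10:
        raise AnalysisError("correction needs at least 10 frames")
    data = stack.data
    frame_means = data.mean(axis=(1, 2))
    if np.any(frame_means <= 0):
        raise AnalysisError("frames with non-positive mean intensity")
    # bleach trend: exponential fit to the frame means rather than the raw
    # per-frame values — in a field of view a few wavelengths across the mean
    # oscillates with the pattern phase, and dividing by it frame-by-frame
    # would imprint a spurious global oscillation
    t_idx = np.arange(stack.n_frames)
    slope, intercept = np.polyfit(t_idx, np.log(frame_means), 1)
    bleach = np.exp(intercept + slope * t_idx)
    norm = data * (bleach[0] / bleach)[:, None, None]

    # robust temporal average: a trimmed mean suppresses transiently bright
    # moving features like the plain median, but unlike the median it has no
    # O(amplitude) bias for periodic signals sampled at few phases per period
    lo, hi = np.quantile(norm, [0.2, 0.8], axis=0)
    clipped = np.clip(norm, lo[None], hi[None])
    med = clipped.mean(axis=0)
    baseline = gaussian_filter(med, sigma=static_sigma_px, mode="nearest")
    static = med - baseline  # specks and scratches, zero-mean on smooth scales

    sigma = illum_sigma_frac * min(data.shape[1], data.shape[2])
    avg = norm.mean(axis=0) - static
    illum = gaussian_filter(avg, sigma=sigma, mode="nearest")
    illum = illum / illum.max()
    n_floor = int((illum < illum_floor).sum())
    if n_floor:
        raise AnalysisError(
            f"illumination field has {n_floor} pixels below the floor {illum_floor}; "
            "increase illum_floor or crop the field of view"
        )

    corrected = (norm - static[None]) / illum[None]
    return stack.copy_with(corrected)


# ---------------------------------------------------------------------------
# Length / time scales
# ---------------------------------------------------------------------------

def _radial_average(img: np.ndarray) -> np.ndarray:
    ny, nx = img.shape
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    r = np.sqrt(y[:, None] ** 2 + x[None, :] ** 2)
    rbin = r.astype(int)
    shifted = np.fft.fftshift(img)
    counts = np.bincount(rbin.ravel())
    sums = np.bincount(rbin.ravel(), weights=shifted.ravel())
    return sums / np.maximum(counts, 1)


def _directional_profile(ac: np.ndarray, theta: float) -> np.ndarray:
    """Sample the (unshifted) autocorrelation along direction θ from the
    central peak by bilinear interpolation, out to half the smaller side."""
    ny, nx = ac.shape
    shifted = np.fft.fftshift(ac)
    cy, cx = ny // 2, nx // 2
    rmax = min(ny, nx) // 2 - 1
    rs = np.arange(rmax)
    ys = cy + rs * np.sin(theta)
    xs = cx + rs * np.cos(theta)
    y0 = np.clip(np.floor(ys).astype(int), 0, ny - 2)
    x0 = np.clip(np.floor(xs).astype(int), 0, nx - 2)
    fy = ys - y0
    fx = xs - x0
    return ((1 - fy) * (1 - fx) * shifted[y0, x0]
            + (1 - fy) * fx * shifted[y0, x0 + 1]
            + fy * (1 - fx) * shifted[y0 + 1, x0]
            + fy * fx * shifted[y0 + 1, x0 + 1])


def _first_side_maximum(curve: np.ndarray, floor: float) -> int | None:
    """Index of the first local maximum after the initial descent from the
    central peak, if it exceeds the floor."""
    n = len(curve)
    i = 1
    while i < n - 1 and curve[i] <= curve[i - 1]:
        i += 1
    # now climbing (or flat); find the local max
    while i < n - 1 and curve[i + 1] >= curve[i]:
        i += 1
    if i <= 1 or i >= n - 1:
        return None
    if curve[i] < floor:
        return None
    return i


def spatial_wavelength(
    stack: MovieStack,
    n_frames: int = 10,
    floor: float = 0.05,
) -> float | None:
    """Dominant pattern wavelength (μm) from per-frame 2D autocorrelation.

    Per frame, the autocorrelation is sampled radially from the central peak
    along the dominant pattern orientation (from the spectral peak), where
    its first side maximum sits at one wavelength irrespective of propagation
    direction; a straight radial average would smear an oriented wave into a
    Bessel profile with a shifted side lobe.  The median over n_frames evenly
    spaced frames is returned, or None if no side maximum exceeds the floor.
    """
    if stack.n_frames < n_frames:
        raise AnalysisError(f"need at least {n_frames} frames")
    idx = np.linspace(0, stack.n_frames - 1, n_frames).astype(int)
    peaks = []
    ny, nx = stack.data.shape[1:]
    ones = np.ones((ny, nx))
    Fw = np.fft.fft2(ones, (2 * ny, 2 * nx))
    counts = np.fft.ifft2(np.abs(Fw) ** 2).real
    counts = np.maximum(counts, 1e-9)
    for i in idx:
        frame = stack.data[i]
        f = frame - frame.mean()
        # unbiased linear (zero-padded) autocorrelation avoids the side-lobe
        # shift that circular wrap-around causes at non-integer wave counts
        F = np.fft.fft2(f, (2 * ny, 2 * nx))
        P = np.abs(F) ** 2
        ac = np.fft.ifft2(P).real / counts
        if ac.flat[0] <= 0:
            continue
        ac /= ac.flat[0]
        # dominant orientation from the spectral peak (DC region excluded)
        Ps = np.fft.fftshift(P)
        cy, cx = ny, nx
        Ps[cy - 1: cy + 2, cx - 1: cx + 2] = 0
        ky, kx = np.unravel_index(np.argmax(Ps), Ps.shape)
        theta = np.arctan2(ky - cy, kx - cx)
        prof = _directional_profile(ac, theta)[: min(ny, nx) // 2]
        k = _first_side_maximum(prof, floor)
        if k is not None:
            peaks.append(k)
    if len(peaks) < max(1, n_frames // 2):
        return None
    return float(np.median(peaks) * stack.pixel_size)


def _autocorr_1d(x: np.ndarray) -> np.ndarray:
    """Biased autocorrelation of a mean-subtracted trace, normalized at lag 0."""
    x = x - x.mean()
    n = len(x)
    f = np.fft.rfft(x, 2 * n)
    ac = np.fft.irfft(f * np.conj(f))[:n]
    if ac[0] <= 0:
        return np.zeros(n)
    return ac / ac[0]


def temporal_period(
    source,
    n_kymo: int = 20,
    center_fraction: float = 0.7,
    min_height: float = 0.05,
) -> float | None:
    """Dominant oscillation period (s).

    For a MovieStack, n_kymo kymographs (half x–t, half y–t) are drawn evenly
    over the central region; each contributes a temporal autocorrelation
    curve averaged along its spatial line.  The pointwise median curve's
    first maximum after lag 0 gives the period.  For a 2D array input
    (space × time) the rows of that kymograph are used directly.
    """
    if isinstance(source, MovieStack):
        data = source.data
        dt = source.frame_interval
        nt, ny, nx = data.shape
        lo_y, hi_y = int(ny * (1 - center_fraction) / 2), int(ny * (1 + center_fraction) / 2)
        lo_x, hi_x = int(nx * (1 - center_fraction) / 2), int(nx * (1 + center_fraction) / 2)
        rows = np.linspace(lo_y, hi_y - 1, n_kymo // 2).astype(int)
        cols = np.linspace(lo_x, hi_x - 1, n_kymo - n_kymo // 2).astype(int)
        kymos = [data[:, r, lo_x:hi_x].T for r in rows] + \
                [data[:, lo_y:hi_y, c].T for c in cols]
    else:
        raise AnalysisError("use temporal_period_kymo for raw kymograph arrays")
    curves = []
    for k in kymos:
        acs = np.array([_autocorr_1d(row) for row in k])
        curves.append(acs.mean(axis=0))
    med = np.median(np.array(curves), axis=0)
    return _period_from_curve(med, dt, min_height)


def temporal_period_kymo(kymo: np.ndarray, frame_interval: float,
                         min_height: float = 0.05) -> float | None:
    """Dominant period from a single kymograph (space × time)."""
    kymo = np.asarray(kymo, dtype=float)
    acs = np.array([_autocorr_1d(row) for row in kymo])
    return _period_from_curve(acs.mean(axis=0), frame_interval, min_height)


def _period_from_curve(curve: np.ndarray, dt: float, min_height: float) -> float | None:
    k = _first_side_maximum(curve, min_height)
    if k is None:
        return None
    return float(k * dt)


# ---------------------------------------------------------------------------
# Dual-plane correlation
# ---------------------------------------------------------------------------

def topbottom_correlation(
    top: MovieStack,
    bottom: MovieStack,
    cell_size: float = 10.0,
    window: float | None = None,
    thresholds: tuple[float, float] = (0.7, -0.3),
    time_offset_tol: float = 0.1,
) -> CorrelationReport:
    """Per-subregion Pearson correlation between top and bottom time traces.

    The field of view is divided into whole cells of cell_size × cell_size
    μm² (partial edge cells dropped); each cell's spatially averaged,
    mean-subtracted time trace over the window is correlated between the two
    planes.  Cells with a constant trace are undefined and excluded from the
    classified fractions.
    """
    if top.data.shape != bottom.data.shape:
        raise AnalysisError("top and bottom stacks must have identical shapes")
    if abs(top.pixel_size - bottom.pixel_size) > 1e-9 or \
       abs(top.frame_interval - bottom.frame_interval) > time_offset_tol:
        raise AnalysisError("top and bottom stacks must share calibration")
    n_px = int(round(cell_size / top.pixel_size))
    if n_px < 1:
        raise AnalysisError("cell_size below one pixel")
    nt, ny, nx = top.data.shape
    ncy, ncx = ny // n_px, nx // n_px
    if ncy == 0 or ncx == 0:
        raise AnalysisError("field of view smaller than one correlation cell")
    if window is not None:
        n_frames = max(2, int(round(window / top.frame_interval)) + 1)
        n_frames = min(n_frames, nt)
    else:
        n_frames = nt

    def cell_traces(stack):
        d = stack.data[:n_frames, : ncy * n_px, : ncx * n_px]
        d = d.reshape(n_frames, ncy, n_px, ncx, n_px).mean(axis=(2, 4))
        return d.reshape(n_frames, -1).T  # (ncells, time)

    a = cell_traces(top)
    b = cell_traces(bottom)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a ** 2).sum(axis=1))
    nb = np.sqrt((b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (a * b).sum(axis=1) / (na * nb)
    corr[(na == 0) | (nb == 0)] = np.nan
    corr = corr.reshape(ncy, ncx)
    n_undef = int(np.isnan(corr).sum())
    finite = corr[~np.isnan(corr)]
    fractions = classify_correlation(finite, thresholds) if finite.size else \
        {"correlated": 0.0, "anticorrelated": 0.0, "neither": 0.0}
    hist = np.histogram(finite, bins=np.linspace(-1, 1, 41))
    centers = (np.arange(ncx) + 0.5) * n_px * top.pixel_size
    centers_y = (np.arange(ncy) + 0.5) * n_px * top.pixel_size
    return CorrelationReport(
        cell_size=n_px * top.pixel_size,
        cell_centers_x=centers, cell_centers_y=centers_y,
        correlations=corr, thresholds=thresholds, fractions=fractions,
        histogram=hist, n_undefined=n_undef,
        window=(0.0, (n_frames - 1) * top.frame_interval),
    )


def pair_correlation_1d(
    top_series: np.ndarray,
    bottom_series: np.ndarray,
    dx: float,
    frame_interval: float,
    cell_size: float = 10.0,
    window: float | None = None,
    thresholds: tuple[float, float] = (0.7, -0.3),
) -> CorrelationReport:
    """Subregion correlation between two (nt, nx) membrane time series from a
    slice simulation — the 1D analogue of :func:`topbottom_correlation`."""
    top_series = np.asarray(top_series, dtype=float)
    bottom_series = np.asarray(bottom_series, dtype=float)
    if top_series.shape != bottom_series.shape or top_series.ndim != 2:
        raise AnalysisError("series must be two equal-shape (nt, nx) arrays")
    nt, nx = top_series.shape
    n_px = max(1, int(round(cell_size / dx)))
    ncx = nx // n_px
    if ncx == 0:
        raise AnalysisError("domain shorter than one correlation cell")
    n_frames = nt if window is None else min(nt, max(2, int(round(window / frame_interval)) + 1))

    def traces(series):
        d = series[:n_frames, : ncx * n_px].reshape(n_frames, ncx, n_px).mean(axis=2)
        return d.T

    a, b = traces(top_series), traces(bottom_series)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a ** 2).sum(axis=1))
    nb = np.sqrt((b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (a * b).sum(axis=1) / (na * nb)
    corr[(na == 0) | (nb == 0)] = np.nan
    corr = corr.reshape(1, ncx)
    finite = corr[~np.isnan(corr)]
    fractions = classify_correlation(finite, thresholds) if finite.size else \
        {"correlated": 0.0, "anticorrelated": 0.0, "neither": 0.0}
    return CorrelationReport(
        cell_size=n_px * dx,
        cell_centers_x=(np.arange(ncx) + 0.5) * n_px * dx,
        cell_centers_y=np.array([0.0]),
        correlations=corr, thresholds=thresholds, fractions=fractions,
        histogram=np.histogram(finite, bins=np.linspace(-1, 1, 41)),
        n_undefined=int(np.isnan(corr).sum()),
        window=(0.0, (n_frames - 1) * frame_interval),
    )


def classify_correlation(values, thresholds: tuple[float, float] = (0.7, -0.3)) -> dict:
    """Fractions of correlated (> hi), anticorrelated (< lo), and neither.

    Strict inequalities: boundary values count as 'neither'."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise AnalysisError("empty correlation input")
    if np.any(values < -1 - 1e-9) or np.any(values > 1 + 1e-9):
        raise AnalysisError("correlation values must lie in [-1, 1]")
    hi, lo = thresholds
    n = values.size
    n_hi = int((values > hi).sum())
    n_lo = int((values < lo).sum())
    return {
        "correlated": n_hi / n,
        "anticorrelated": n_lo / n,
        "neither": (n - n_hi - n_lo) / n,
    }


# ---------------------------------------------------------------------------
# Pattern classification (complex demodulation)
# ---------------------------------------------------------------------------

def _dominant_frequency(signal_2d: np.ndarray, dt: float,
                        min_contrast: float = 4.0) -> tuple[float, int] | None:
    """Dominant nonzero temporal frequency of (space..., time) data by the
    spatially averaged power spectrum; None if no line stands out."""
    s = signal_2d - signal_2d.mean(axis=-1, keepdims=True)
    nt = s.shape[-1]
    win = np.hanning(nt)
    spec = np.abs(np.fft.rfft(s * win, axis=-1)) ** 2
    power = spec.reshape(-1, spec.shape[-1]).mean(axis=0)
    power[0] = 0.0
    if len(power) < 3:
        return None
    k = int(np.argmax(power))
    if k == 0:
        return None
    background = np.median(power[1:])
    if background <= 0 or power[k] < min_contrast * background:
        if power[k] <= 0:
            return None
        # weak but possibly genuine line; accept only clear peaks
        return None
    freqs = np.fft.rfftfreq(nt, d=dt)
    return float(freqs[k]), k


def _demodulate(signal_nd: np.ndarray, dt: float, f0: float) -> np.ndarray:
    t = np.arange(signal_nd.shape[-1]) * dt
    win = np.hanning(len(t))
    s = signal_nd - signal_nd.mean(axis=-1, keepdims=True)
    return (s * win * np.exp(-2j * np.pi * f0 * t)).sum(axis=-1)


@dataclass
class ClassifierThresholds:
    """Decision thresholds of the pattern classifier."""

    standing_min_k_bins: int = 2      # spatial structure needed to call standing
    traveling_min_k_bins: int = 4     # short-wavelength structure needed to
                                      # call traveling (longer-wavelength
                                      # asymmetric motion is a phase wave and
                                      # classifies as homogeneous)
    traveling_asymmetry: float = 0.5  # windowed |left-right| power asymmetry
                                      # above this → traveling, below → standing
    min_cycles: float = 3.0           # required duration in periods
    n_windows: int = 8                # spatial windows for the asymmetry test


def _spacetime_metrics(kymo: np.ndarray, dx: float, dt: float,
                       n_windows: int) -> dict | None:
    """Dominant (k, ω) line of a kymograph and the per-window propagation
    asymmetry at that line.

    The asymmetry D ∈ [−1, 1] compares spectral power on the two diagonals
    (k > 0, ω > 0)+(k < 0, ω < 0) vs the opposite pair: a single traveling
    wave puts all power on one diagonal (|D| → 1), a standing wave balances
    them (D → 0).  Counter-propagating trains in different parts of the
    domain are resolved by evaluating D in spatial windows.
    """
    nx, nt = kymo.shape
    s = kymo - kymo.mean(axis=1, keepdims=True)
    win_t = np.hanning(nt)
    win_x = np.hanning(nx)
    F = np.fft.fft2(s * win_x[:, None] * win_t[None, :])
    P = np.abs(F) ** 2
    # temporal marginal (ω > 0 half)
    nw = nt // 2
    Pw = P.sum(axis=0)[:nw]
    Pw[0] = 0.0
    if nw < 3 or Pw.max() <= 0:
        return None
    w0 = int(np.argmax(Pw))
    if w0 == 0 or Pw[w0] < 4.0 * np.median(Pw[1:]):
        return None
    # spatial marginal at the ω0 band (±1 bin), folded over ±k
    band = P[:, max(1, w0 - 1): w0 + 2].sum(axis=1)
    nk = nx // 2
    Pk = band[:nk].copy()
    Pk[1:] += band[-1: -nk: -1]
    k0 = int(np.argmax(Pk))
    # per-window diagonal asymmetry at (±k0, ±ω0)
    asym = []
    wlen = nx // n_windows
    ds = []
    if wlen >= 4:
        for iw in range(n_windows):
            seg = s[iw * wlen: (iw + 1) * wlen]
            Fw = np.fft.fft2(seg * np.hanning(seg.shape[0])[:, None] * win_t[None, :])
            Pww = np.abs(Fw) ** 2
            nkw, nww = seg.shape[0] // 2, nt // 2
            # quadrants excluding the k=0 and ω=0 lines
            q_pp = Pww[1:nkw, 1:nww].sum()       # k>0, ω>0
            q_mp = Pww[nkw + 1:, 1:nww].sum()    # k<0, ω>0
            tot = q_pp + q_mp
            if tot > 0:
                ds.append((q_pp - q_mp) / tot)
    D = float(np.median(np.abs(ds))) if ds else None
    return {"w0_bin": w0, "k0_bin": k0, "frequency": w0 / (nt * dt),
            "wavenumber": 2 * np.pi * k0 / (nx * dx), "asymmetry": D,
            "power_contrast": float(Pw[w0] / max(np.median(Pw[1:]), 1e-300))}


def classify_pattern_kymo(
    kymo: np.ndarray,
    dx: float,
    dt: float,
    thresholds: ClassifierThresholds | None = None,
) -> PatternLabel:
    """Classify a kymograph (space × time) by its space-time spectrum.

    Decision order: no clear temporal line → indeterminate; dominant spatial
    wavenumber within homogeneous_k_bins of zero → homogeneous oscillation
    (this includes phase waves, whose apparent motion carries no lateral
    mass transport); otherwise the windowed propagation asymmetry separates
    traveling (one-sided power) from standing (balanced) waves.
    """
    th = thresholds or ClassifierThresholds()
    kymo = np.asarray(kymo, dtype=float)
    if kymo.ndim != 2:
        raise AnalysisError("kymograph must be 2D (space, time)")
    m = _spacetime_metrics(kymo, dx, dt, th.n_windows)
    if m is None:
        return PatternLabel("indeterminate", reason="no dominant temporal frequency")
    f0 = m["frequency"]
    nt = kymo.shape[1]
    if (nt - 1) * dt * f0 < th.min_cycles:
        return PatternLabel("indeterminate", frequency=f0, period=1 / f0,
                            reason="duration shorter than required number of cycles")
    # supporting demodulation metrics
    Z = _demodulate(kymo, dt, f0)
    S1, S2, g_mean, g_cv = _phase_metrics(Z, dx)
    k0, D = m["k0_bin"], m["asymmetry"]
    if D is not None and k0 >= th.standing_min_k_bins and D <= th.traveling_asymmetry:
        label = "standing_wave"
    elif D is not None and k0 >= th.traveling_min_k_bins and D > th.traveling_asymmetry:
        label = "traveling_wave"
    elif k0 < th.traveling_min_k_bins:
        # little short-wavelength structure: in-phase patches, possibly with
        # phase gradients (phase waves) — no lateral mass transport implied
        label = "homogeneous_oscillation"
    else:
        label = "indeterminate"
    return PatternLabel(
        pattern_class=label, frequency=f0, period=1 / f0,
        phase_spread=S1, phase_doubling_spread=S2,
        grad_mean=g_mean, grad_cv=g_cv,
        reason="" if label != "indeterminate" else "propagation asymmetry unavailable",
    )


def classify_pattern(
    source,
    thresholds: ClassifierThresholds | None = None,
) -> PatternLabel:
    """Classify a MovieStack or a (kymo, dx, dt) tuple.

    Movie stacks are reduced to a kymograph along the dominant pattern
    orientation (through the image centre); spatially structureless movies
    fall through to the homogeneous branch directly.
    """
    th = thresholds or ClassifierThresholds()
    if isinstance(source, tuple) and len(source) == 3:
        return classify_pattern_kymo(*source, thresholds=thresholds)
    if not isinstance(source, MovieStack):
        raise AnalysisError("source must be a MovieStack or (kymo, dx, dt)")
    stack = source
    data = stack.data
    nt, ny, nx = data.shape
    # dominant orientation from the time-summed spatial spectrum
    f = data - data.mean(axis=0, keepdims=True)
    P = np.abs(np.fft.fft2(f, axes=(1, 2))) ** 2
    Ps = np.fft.fftshift(P.sum(axis=0))
    cy, cx = ny // 2, nx // 2
    Ps[cy - 1: cy + 2, cx - 1: cx + 2] = 0
    ky, kx = np.unravel_index(np.argmax(Ps), Ps.shape)
    theta = np.arctan2(ky - cy, kx - cx)
    # kymograph along the dominant direction through the centre
    rmax = min(ny, nx) // 2 - 1
    rs = np.arange(-rmax, rmax)
    ys = np.clip((cy + rs * np.sin(theta)).round().astype(int), 0, ny - 1)
    xs = np.clip((cx + rs * np.cos(theta)).round().astype(int), 0, nx - 1)
    kymo = data[:, ys, xs].T  # (space, time)
    return classify_pattern_kymo(kymo, stack.pixel_size, stack.frame_interval,
                                 thresholds=thresholds)


def _phase_metrics(Z: np.ndarray, dx: float) -> tuple[float, float, float, float]:
    """Supporting metrics of the demodulated field: circular phase spread,
    doubled-phase spread, and |∇φ| statistics (amplitude-weighted)."""
    A = np.abs(Z)
    if A.max() <= 0:
        return 1.0, 1.0, 0.0, float("inf")
    w = A / A.sum()
    phi = np.angle(Z)
    S1 = 1 - float(np.abs((w * np.exp(1j * phi)).sum()))
    S2 = 1 - float(np.abs((w * np.exp(2j * phi)).sum()))
    dphi = np.angle(Z[1:] * np.conj(Z[:-1])) / dx
    gmag = np.abs(dphi)
    wt = 0.5 * (A[1:] + A[:-1])
    wt = wt / wt.sum()
    g_mean = float((wt * gmag).sum())
    g_var = float((wt * (gmag - g_mean) ** 2).sum())
    g_cv = float(np.sqrt(g_var) / g_mean) if g_mean > 0 else float("inf")
    return S1, S2, g_mean, g_cv
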