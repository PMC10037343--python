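"""Voltage-sensitive-dye signal chain.

dF/F0 normalization, photobleaching fit (2.5-Hz low-passed ROI trace fitted
with a quadratic in time) and subtraction, the ln(a)-vs-pre-exposure
regression across trials, Fourier-domain patterned-noise (moire) removal,
and 2-D Gaussian spatial smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigurationError


@dataclass
class FluorescenceSequence:
    """T x H x W fluorescence stack, in counts or dF/F units.

    ``valid`` marks pixels with a usable baseline; invalid pixels hold 0.
    """

    frames: np.ndarray
    dt_ms: float
    preexposure_s: float = 0.0
    units: str = "counts"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be T x H x W with T >= 1")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if self.valid is None:
            self.valid = np.ones(self.frames.shape[1:], dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def rate_hz(self) -> float:
        return 1000.0 / self.dt_ms

    @property
    def t_abs_s(self) -> np.ndarray:
        """Absolute time axis (seconds since shutter opening)."""
        return self.preexposure_s + np.arange(self.n_frames) * self.dt_ms / 1000.0

    def roi_trace(self, roi: np.ndarray | None = None) -> np.ndarray:
        """Mean trace over a boolean ROI (default: all valid pixels)."""
        mask = self.valid if roi is None else (np.asarray(roi, dtype=bool) & self.valid)
        if not mask.any():
            raise ValueError("empty ROI")
        return self.frames[:, mask].mean(axis=1)


@dataclass
class BleachFit:
    """Quadratic photobleaching fit of the low-passed ROI-mean dF/F trace.

    ``poly`` is ``(a, b, c)`` on the absolute time axis (offset by the
    pre-exposure); ``roi_trace`` is the fitted trace evaluated per frame.
    """

    poly: tuple[float, float, float]
    cutoff_hz: float
    order: int
    roi_trace: np.ndarray
    preexposure_s: float = 0.0

    @property
    def a(self) -> float:
        return self.poly[0]


def compute_dff(seq: FluorescenceSequence, ref_frame: int) -> FluorescenceSequence:
    """Per-pixel dF/F0 with F0 the mean of the three frames around ``ref_frame``.

    Pixels with F0 <= 0 are flagged invalid (set to 0), not infinite.
    """
    t = seq.n_frames
    if not 1 <= ref_frame <= t - 2:
        raise ValueError(f"ref_frame {ref_frame} leaves no 3-frame window in [0, {t - 1}]")
    f = seq.frames.astype(float)
    f0 = f[ref_frame - 1 : ref_frame + 2].mean(axis=0)
    ok = (f0 > 0) & seq.valid
    dff = np.zeros_like(f)
    dff[:, ok] = (f[:, ok] - f0[ok]) / f0[ok]
    return FluorescenceSequence(
        frames=dff,
        dt_ms=seq.dt_ms,
        preexposure_s=seq.preexposure_s,
        units="dff",
        valid=ok,
    )


def fit_bleach(
    seq: FluorescenceSequence,
    roi: np.ndarray | None = None,
    cutoff_hz: float = 2.5,
    order: int = 4,
) -> BleachFit:
    """Fit the photobleaching trend of a dF/F sequence.

    The ROI-mean trace is low-passed with a zero-phase Butterworth filter
    (``cutoff_hz``, forward-backward) and fitted with a least-squares
    quadratic on the absolute time axis.
    """
    if seq.n_frames < 10:
        raise ValueError("need >= 10 frames to fit the bleach trend")
    if cutoff_hz >= seq.rate_hz / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    trace = seq.roi_trace(roi)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=seq.rate_hz, output="sos")
    t = seq.t_abs_s
    # The cutoff sits far below Nyquist, so on a short trace the filter
    # transient would distort the slow trend itself.  Detrend with a
    # preliminary quadratic, low-pass only the residual (maximal odd-
    # extension padding), and add the trend back: polynomials pass through
    # untouched and the filter still suppresses fast structure.
    pre = np.polyfit(t, trace, deg=2)
    resid = trace - np.polyval(pre, t)
    filtered = np.polyval(pre, t) + signal.sosfiltfilt(sos, resid, padlen=trace.size - 1)
    coeffs = np.polyfit(t, filtered, deg=2)
    fitted = np.polyval(coeffs, t)
    return BleachFit(
        poly=tuple(float(c) for c in coeffs),
        cutoff_hz=cutoff_hz,
        order=order,
        roi_trace=fitted,
        preexposure_s=seq.preexposure_s,
    )


def correct_bleach(seq: FluorescenceSequence, fit: BleachFit) -> FluorescenceSequence:
    """Subtract the fitted bleaching trace from every pixel's time series."""
    if fit.roi_trace.shape[0] != seq.n_frames:
        raise ValueError(
            f"bleach fit has {fit.roi_trace.shape[0]} frames, sequence has {seq.n_frames}"
        )
    frames = seq.frames - fit.roi_trace[:, None, None]
    frames[:, ~seq.valid] = 0.0
    return FluorescenceSequence(
        frames=frames,
        dt_ms=seq.dt_ms,
        preexposure_s=seq.preexposure_s,
        units=seq.units,
        valid=seq.valid.copy(),
    )


@dataclass
class PreexposureRegression:
    """Degree-2 polynomial regression of ln(a) on pre-exposure time."""

    coeffs: np.ndarray
    cov: np.ndarray
    preexposure_s: np.ndarray
    log_a: np.ndarray

    def predict(self, t_pre_s: np.ndarray) -> np.ndarray:
        return np.polyval(self.coeffs, np.asarray(t_pre_s, dtype=float))

    def confidence_band(self, t_pre_s: np.ndarray, n_sigma: float = 1.96) -> np.ndarray:
        """Half-width of the prediction confidence band at each time."""
        t = np.asarray(t_pre_s, dtype=float)
        x = np.vander(t, 3)
        var = np.einsum("ij,jk,ik->i", x, self.cov, x)
        return n_sigma * np.sqrt(np.maximum(var, 0.0))


def bleach_vs_preexposure(
    fits: list[BleachFit], preexposure_s: list[float] | None = None
) -> PreexposureRegression:
    """Regress ln(a) (leading bleach-fit coefficient) on pre-exposure time.

    Trials with ``a <= 0`` are excluded with a warning; at least 3 usable
    trials at distinct pre-exposure times are required.
    """
    if preexposure_s is None:
        preexposure_s = [f.preexposure_s for f in fits]
    if len(fits) != len(preexposure_s):
        raise ValueError("fits and preexposure_s must have equal length")
    tpre, log_a = [], []
    for f, tp in zip(fits, preexposure_s):
        if f.a <= 0:
            warnings.warn(f"excluding trial with non-positive a={f.a:.3g}", stacklevel=2)
            continue
        tpre.append(float(tp))
        log_a.append(np.log(f.a))
    if len(tpre) < 3:
        raise ValueError(f"need >= 3 trials with a > 0, have {len(tpre)}")
    tpre = np.asarray(tpre)
    log_a = np.asarray(log_a)
    if np.unique(tpre).size < 3:
        raise ValueError("pre-exposure times are rank deficient for a quadratic fit")
    coeffs, cov = np.polyfit(tpre, log_a, deg=2, cov="unscaled" if len(tpre) < 5 else True)
    return PreexposureRegression(coeffs=coeffs, cov=cov, preexposure_s=tpre, log_a=log_a)


@dataclass(frozen=True)
class NoiseMask:
    """Fourier bins (cycles/px pairs ``(fy, fx)``) to null, excluding DC.

    The conjugate-symmetric closure is applied automatically when the mask
    is rasterized, so filtered images remain real.
    """

    freqs: tuple = ()

    def __post_init__(self) -> None:
        for fy, fx in self.freqs:
            if abs(fy) < 1e-12 and abs(fx) < 1e-12:
                raise ConfigurationError("freqs: DC must not be masked")

    def to_indices(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Integer FFT bin indices (with conjugates) for an H x W frame."""
        h, w = shape
        iy, ix = [], []
        for fy, fx in self.freqs:
            ky = int(round(fy * h)) % h
            kx = int(round(fx * w)) % w
            if ky == 0 and kx == 0:
                raise ConfigurationError("freqs: a bin rounds to DC")
            for ky_, kx_ in ((ky, kx), ((-ky) % h, (-kx) % w)):
                iy.append(ky_)
                ix.append(kx_)
        return np.asarray(iy), np.asarray(ix)


def remove_patterned_noise(
    seq: FluorescenceSequence, mask: NoiseMask
) -> FluorescenceSequence:
    """Null the masked spatial-frequency bins of every frame (inverse FFT).

    Per frame: 2-D FFT, set the masked bins and their conjugates to zero,
    inverse transform, keep the real part.  Unmasked bins are untouched.
    """
    if not mask.freqs:
        return FluorescenceSequence(
            frames=seq.frames.copy(),
            dt_ms=seq.dt_ms,
            preexposure_s=seq.preexposure_s,
            units=seq.units,
            valid=seq.valid.copy(),
        )
    iy, ix = mask.to_indices(seq.frames.shape[1:])
    spec = np.fft.fft2(seq.frames, axes=(1, 2))
    spec[:, iy, ix] = 0.0
    frames = np.fft.ifft2(spec, axes=(1, 2)).real
    return FluorescenceSequence(
        frames=frames,
        dt_ms=seq.dt_ms,
        preexposure_s=seq.preexposure_s,
        units=seq.units,
        valid=seq.valid.copy(),
    )


def gaussian_kernel(kernel_px: int, sigma_px: float) -> np.ndarray:
    """Normalized truncated 2-D Gaussian kernel of odd size ``kernel_px``."""
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    ax = np.arange(kernel_px) - kernel_px // 2
    g = np.exp(-(ax**2) / (2 * sigma_px**2))
    k = np.outer(g, g)
    return k / k.sum()


def spatial_smooth(
    seq: FluorescenceSequence, kernel_px: int = 5, sigma_px: float | None = None
) -> FluorescenceSequence:
    """Per-frame convolution with a normalized truncated Gaussian (5x5 default).

    ``sigma_px`` defaults to ``kernel_px / 5`` (about 1 px for the 5x5
    kernel).  Constant frames are unchanged.
    """
    if sigma_px is None:
        sigma_px = kernel_px / 5.0
    k = gaussian_kernel(kernel_px, sigma_px)
    frames = np.empty_like(seq.frames, dtype=float)
    for i in range(seq.n_frames):
        frames[i] = ndimage.convolve(seq.frames[i].astype(float), k, mode="reflect")
    return FluorescenceSequence(
        frames=frames,
        dt_ms=seq.dt_ms,
        preexposure_s=seq.preexposure_s,
        units=seq.units,
        valid=seq.valid.copy(),
    )
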