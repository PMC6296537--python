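"""Per-pixel depth-resolved attenuation and backscatter estimation.

Both estimators work along individual A-lines of a polar frame under the
single-scattering model

    I(z) = A * beta * mu * exp(-2 * integral_0^z mu du),

where ``mu`` (mm^-1) is the attenuation coefficient and ``beta`` the
(relative) backscatter efficiency.

Attenuation is estimated depth-resolved from the ratio of local intensity to
the remaining integrated tail intensity::

    mu[i, j] = I[i, j] / (2 * dz * (sum_{k>j} I[i, k] + I[i, j] / 2))

The half-sample term makes the denominator a trapezoidal integral of the
remaining signal; without it the discrete sum carries a multiplicative bias
of (e^{2 mu dz} - 1)/(2 mu dz), which exceeds 2% for mu = 4 mm^-1 at
dz = 5 um. With it the bias is tanh(mu dz)/(mu dz) - 1 ~ -(mu dz)^2 / 3,
negligible at physiological mu.

Because the tail integral is truncated at the frame bottom, the deepest
``tail_guard_fraction`` of samples is flagged invalid (boundary artifact);
an extrapolated-tail mode is available instead via ``tail_mode``.

A small uniform pre-filter (default 3 A-lines x 3 depth samples) is applied
before estimation. For noiseless exponential decay it multiplies every depth
sample by the same constant and cancels exactly in the estimator ratio; under
fully developed speckle it pools ~9 independent speckle cells, pulling the
median of the per-pixel estimate to within a few percent of truth (a single
exponential draw would bias the median by ln 2). Pass ``smooth=None`` to
disable.

The backscatter term is the log-scale residual of the model after removing
attenuation and accumulated transmission::

    b[i, j] = log10( I[i, j] / (mu[i, j] * T[i, j]) ) + gain,

with the transmission estimated from tail energies,
``T[i, j] = sum_{k>=j} I[i, k] / sum_{k>=j0} I[i, k]`` (j0 = catheter
offset). ``b`` is dimensionless; the additive ``gain`` is an arbitrary
display offset (default 5.0) and absolute scale agreement with any
particular scanner software is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AnalysisError
from .oct_io import PolarFrame

__all__ = [
    "AttenuationMap",
    "BackscatterMap",
    "estimate_attenuation",
    "estimate_backscatter",
    "estimate_noise_floor",
]

DEFAULT_TAIL_GUARD = 0.1
DEFAULT_MU_CAP = 20.0  # mm^-1; bounds speckle-driven outliers
DEFAULT_GAIN = 5.0
DEFAULT_SMOOTH = (3, 3)  # (A-lines, depth samples)


@dataclass(frozen=True)
class AttenuationMap:
    """Per-pixel attenuation estimate (mm^-1) with validity mask.

    ``valid`` is False in the catheter region, the tail-guard region, and
    wherever the estimate is undefined (zero denominator). The
    floor-subtracted, smoothed intensity actually used for estimation is
    kept (``processed``) so that the backscatter estimator sees the same
    signal.
    """

    mu: np.ndarray
    valid: np.ndarray
    axial_pitch_mm: float
    catheter_offset: int
    noise_floor: float
    processed: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.valid.shape:
            raise AnalysisError("mu and valid shapes differ")


@dataclass(frozen=True)
class BackscatterMap:
    """Per-pixel log-scale backscatter term with validity mask.

    ``b`` is NaN wherever invalid.
    """

    b: np.ndarray
    valid: np.ndarray
    gain: float


def estimate_noise_floor(frame: PolarFrame) -> float:
    """Default per-frame noise floor: median intensity of the catheter
    interior annulus (depth columns before ``catheter_offset``).

    Returns 0.0 when the frame has no catheter region.
    """
    if frame.catheter_offset <= 0:
        return 0.0
    return float(np.median(frame.intensity[:, : frame.catheter_offset]))


def _smooth(arr: np.ndarray, smooth: tuple[int, int] | None) -> np.ndarray:
    if smooth is None:
        return arr
    # direct separable convolution; uniform_filter's running-sum algorithm
    # cancels catastrophically over OCT's huge dynamic range
    out = arr
    for axis, size in enumerate(smooth):
        if size > 1:
            weights = np.full(size, 1.0 / size)
            out = ndimage.correlate1d(out, weights, axis=axis, mode="nearest")
    return out


def estimate_attenuation(
    frame: PolarFrame,
    tail_guard_fraction: float = DEFAULT_TAIL_GUARD,
    noise_floor: float | None = None,
    *,
    smooth: tuple[int, int] | None = DEFAULT_SMOOTH,
    mu_cap: float = DEFAULT_MU_CAP,
    tail_mode: str = "guard",
) -> AttenuationMap:
    """Estimate the depth-resolved attenuation coefficient per pixel.

    Parameters
    ----------
    frame
        Polar frame to analyse.
    tail_guard_fraction
        Fraction of the deepest samples per A-line flagged invalid
        (``tail_mode="guard"``); must satisfy ``0 <= f < 1``.
    noise_floor
        Scalar subtracted from all intensities before integration
        (negative residuals clamped to 0). ``None`` selects the catheter
        annulus median via :func:`estimate_noise_floor`.
    smooth
        Uniform pre-filter size ``(n_alines, n_depth)`` or ``None``.
    mu_cap
        Upper bound applied to valid estimates (mm^-1).
    tail_mode
        ``"guard"`` (default) masks the deepest samples; ``"extrapolate"``
        appends a geometric tail fitted on the last 32 samples instead of
        guarding.

    Returns
    -------
    AttenuationMap
        ``mu`` is finite and in ``[0, mu_cap]`` wherever valid; an all-zero
        A-line is entirely invalid (no exception raised).
    """
    if not 0 <= tail_guard_fraction < 1:
        raise AnalysisError(f"tail_guard_fraction must be in [0, 1), got {tail_guard_fraction}")
    if tail_mode not in ("guard", "extrapolate"):
        raise AnalysisError(f"unknown tail_mode {tail_mode!r}")

    floor = estimate_noise_floor(frame) if noise_floor is None else float(noise_floor)
    intensity = np.asarray(frame.intensity, dtype=np.float64)
    residual = np.clip(intensity - floor, 0.0, None)
    residual = _smooth(residual, smooth)

    n_alines, n_depth = residual.shape
    dz = frame.axial_pitch_mm

    # Exclusive reverse cumulative sum: tail[i, j] = sum_{k > j} residual[i, k]
    inclusive = np.cumsum(residual[:, ::-1], axis=1)[:, ::-1]
    tail = inclusive - residual

    if tail_mode == "extrapolate":
        tail = tail + _geometric_tail(residual)

    denom = 2.0 * dz * (tail + 0.5 * residual)
    valid = denom > 0
    mu = np.zeros_like(residual)
    np.divide(residual, denom, out=mu, where=valid)

    cols = np.arange(n_depth)
    valid &= cols[None, :] >= frame.catheter_offset
    if tail_mode == "guard" and tail_guard_fraction > 0:
        n_guard = int(np.ceil(tail_guard_fraction * n_depth))
        valid &= cols[None, :] < n_depth - n_guard

    mu[valid] = np.clip(mu[valid], 0.0, mu_cap)
    mu[~valid] = 0.0
    return AttenuationMap(
        mu=mu,
        valid=valid,
        axial_pitch_mm=dz,
        catheter_offset=frame.catheter_offset,
        noise_floor=floor,
        processed=residual,
    )


def _geometric_tail(residual: np.ndarray) -> np.ndarray:
    """Per-A-line geometric extrapolation of the signal beyond the frame.

    The decay ratio is fitted on the last 32 samples (ratio of the two
    half-window sums); lines where the fit is unusable get no tail.
    """
    n_fit = min(32, residual.shape[1])
    half = n_fit // 2
    if half == 0:
        return np.zeros(residual.shape[0])[:, None] * np.zeros(residual.shape[1])
    recent = residual[:, -half:].sum(axis=1)
    earlier = residual[:, -2 * half : -half].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.power(recent / earlier, 1.0 / half)
    r_hat = np.where(np.isfinite(r_hat), r_hat, 0.0)
    r_hat = np.clip(r_hat, 0.0, 0.9999)
    extra = residual[:, -1] * r_hat / (1.0 - r_hat)
    return extra[:, None] * np.ones((1, residual.shape[1]))


def estimate_backscatter(
    frame: PolarFrame,
    att: AttenuationMap,
    gain: float = DEFAULT_GAIN,
) -> BackscatterMap:
    """Estimate the log-scale backscatter term from a frame and its
    attenuation map (which must derive from the same frame).

    Invalid wherever the attenuation estimate is invalid, the
    floor-subtracted intensity is zero (at or below the noise floor), the
    transmission estimate is zero, or ``mu`` is zero; ``b`` is NaN there.
    Adding a constant to ``gain`` shifts every valid pixel by exactly that
    constant.
    """
    if att.processed.shape != frame.intensity.shape:
        raise AnalysisError("attenuation map does not match frame shape")

    residual = att.processed
    inclusive = np.cumsum(residual[:, ::-1], axis=1)[:, ::-1]  # sum_{k >= j}
    j0 = att.catheter_offset
    total = inclusive[:, j0]
    with np.errstate(divide="ignore", invalid="ignore"):
        transmission = inclusive / total[:, None]

    valid = att.valid & (residual > 0) & (att.mu > 0) & (transmission > 0)
    valid &= np.isfinite(transmission)

    b = np.full_like(residual, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.copyto(
            b,
            np.log10(residual) - np.log10(att.mu) - np.log10(transmission) + gain,
            where=valid,
        )
    return BackscatterMap(b=b, valid=valid, gain=float(gain))
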