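"""Per-pixel FRET index mapping from three-channel sensitized-emission stacks.

The imaging scheme acquires, for every z-frame, three registered channels:

* ``ID`` — donor emission after donor excitation (the quenched donor channel),
* ``IA`` — acceptor emission after direct acceptor excitation,
* ``IF`` — acceptor emission after donor excitation (raw FRET channel).

The raw FRET channel is contaminated by spectral bleed-through from both
fluorophores.  After background subtraction the corrected FRET signal is

    cF(i, j) = IF(i, j) - delta * ID(i, j) - alpha * IA(i, j)

with ``alpha`` and ``delta`` the measured acceptor and donor bleed-through
fractions.  The FRET index is then the ratio metric

    F = (cF * QD * phi) / (qD + cF * QD * phi),       phi = phiD / phiA

where ``qD`` is the background-subtracted donor channel, ``QD`` the donor
quantum yield and ``phi`` the donor/acceptor collection-efficiency ratio.
``F`` is bounded by [0, 1] wherever ``cF >= 0`` and ``qD > 0``, rises with
sensitized emission and falls with quenched-donor signal; for an
intramolecular tension sensor a *low* index means *high* molecular tension.

Per-pixel uncertainty follows from first-order propagation of a shot-noise
variance model ``Var(I) = gain * I`` through both equations; low-intensity
pixels carry high uncertainty and are removed by an acceptor-channel
intensity threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ChannelStack",
    "CalibrationParams",
    "FretMap",
    "bin_image",
    "subtract_background",
    "correct_bleedthrough",
    "compute_fret_index",
    "median_filter_3x3",
    "propagate_uncertainty",
    "threshold_pixels",
    "compute_fret_map",
]

CHANNEL_ORDER = ("ID", "IA", "IF")


class FretDataError(ValueError):
    """Raised when input data violate the pipeline's contracts."""


def _as_stack(arr: np.ndarray) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 2:
        a = a[None, :, :]
    if a.ndim != 3:
        raise FretDataError(f"channel array must be 2-D or 3-D, got shape {a.shape}")
    return a


@dataclass
class ChannelStack:
    """Registered three-channel intensity stack, shape ``(n_frames, H, W)``.

    ``background`` holds one scalar background estimate per channel, in the
    same counts as the raw images.  Pixel coordinates are 0-based row/col.
    """

    ID: np.ndarray
    IA: np.ndarray
    IF: np.ndarray
    background: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ID = _as_stack(self.ID)
        self.IA = _as_stack(self.IA)
        self.IF = _as_stack(self.IF)
        if not (self.ID.shape == self.IA.shape == self.IF.shape):
            raise FretDataError(
                "channel shapes differ: "
                f"ID {self.ID.shape}, IA {self.IA.shape}, IF {self.IF.shape}"
            )
        if self.n_frames < 1:
            raise FretDataError("stack must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.ID.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.ID.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_ORDER:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_ORDER}")
        return getattr(self, name)

    def require_background(self) -> dict[str, float]:
        missing = [c for c in CHANNEL_ORDER if c not in self.background]
        if missing:
            raise FretDataError(f"missing background estimate for channel(s): {missing}")
        return {c: float(self.background[c]) for c in CHANNEL_ORDER}


def estimate_background(stack: ChannelStack, fraction: float = 0.05) -> dict[str, float]:
    """Scalar per-channel background from the darkest ``fraction`` of pixels."""
    if not 0 < fraction <= 1:
        raise FretDataError("fraction must lie in (0, 1]")
    out = {}
    for c in CHANNEL_ORDER:
        vals = np.sort(stack.channel(c).ravel())
        k = max(1, int(round(fraction * vals.size)))
        out[c] = float(vals[:k].mean())
    return out


@dataclass
class CalibrationParams:
    """Calibration constants for index computation and uncertainty.

    alpha, delta
        Acceptor and donor bleed-through fractions in [0, 1).
    QD
        Donor quantum yield in (0, 1].
    phi_ratio
        Collection-efficiency ratio phiD/phiA (> 0); the acceptor quantum
        yield is folded into phiA.
    noise_gain
        Counts per detected photon in the shot-noise variance model
        ``Var(I) = noise_gain * I``.
    threshold_k
        Pixels pass the validity threshold when the raw acceptor channel
        exceeds ``background + threshold_k * sqrt(noise_gain * background)``.
    bin_factor
        Block size for the single binning (down-sample + average) pass.
    """

    alpha: float
    delta: float
    QD: float
    phi_ratio: float
    noise_gain: float = 1.0
    threshold_k: float = 2.0
    bin_factor: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 1 and 0 <= self.delta < 1):
            raise FretDataError("bleed-through fractions must lie in [0, 1)")
        if not (0 < self.QD <= 1):
            raise FretDataError("QD must lie in (0, 1]")
        if self.phi_ratio <= 0:
            raise FretDataError("phi_ratio must be positive")
        if self.noise_gain <= 0:
            raise FretDataError("noise_gain must be positive")
        if int(self.bin_factor) < 1:
            raise FretDataError("bin_factor must be >= 1")
        self.bin_factor = int(self.bin_factor)

    @property
    def gain_factor(self) -> float:
        """QD * phiD/phiA — the scale applied to cF in the index."""
        return self.QD * self.phi_ratio


@dataclass
class FretMap:
    """Result of the index pipeline, all arrays shaped ``(n_frames, H, W)``."""

    F: np.ndarray
    sigmaF: np.ndarray
    valid_mask: np.ndarray
    qD: np.ndarray
    cF: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.F.shape[0]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def bin_image(arr: np.ndarray, factor: int) -> np.ndarray:
    """Down-sample by averaging ``factor x factor`` blocks.

    Trailing rows/columns that do not fill a whole block are cropped.
    Accepts a 2-D image or a 3-D ``(frames, H, W)`` stack.
    """
    if factor < 1:
        raise FretDataError("bin factor must be >= 1")
    if factor == 1:
        return np.asarray(arr, dtype=np.float64).copy()
    a = np.asarray(arr, dtype=np.float64)
    squeeze = a.ndim == 2
    if squeeze:
        a = a[None]
    h, w = a.shape[1:]
    hb, wb = h // factor, w // factor
    if hb == 0 or wb == 0:
        raise FretDataError(f"image {h}x{w} too small for bin factor {factor}")
    a = a[:, : hb * factor, : wb * factor]
    out = a.reshape(a.shape[0], hb, factor, wb, factor).mean(axis=(2, 4))
    return out[0] if squeeze else out


def bin_stack(stack: ChannelStack, factor: int) -> ChannelStack:
    """Apply :func:`bin_image` to all three channels (backgrounds unchanged)."""
    return ChannelStack(
        ID=bin_image(stack.ID, factor),
        IA=bin_image(stack.IA, factor),
        IF=bin_image(stack.IF, factor),
        background=dict(stack.background),
    )


def subtract_background(stack: ChannelStack) -> ChannelStack:
    """Subtract the scalar per-channel background.

    Negative results are retained (not clipped); they are later excluded by
    the validity mask, never silently altered.
    """
    bg = stack.require_background()
    return ChannelStack(
        ID=stack.ID - bg["ID"],
        IA=stack.IA - bg["IA"],
        IF=stack.IF - bg["IF"],
        background={c: 0.0 for c in CHANNEL_ORDER},
    )


def correct_bleedthrough(
    IF: np.ndarray, ID: np.ndarray, IA: np.ndarray, alpha: float, delta: float
) -> np.ndarray:
    """cF = IF - delta*ID - alpha*IA, pixel-wise.

    Over-corrected (negative) pixels are retained and flagged downstream.
    """
    IF, ID, IA = (np.asarray(x, dtype=np.float64) for x in (IF, ID, IA))
    if not (IF.shape == ID.shape == IA.shape):
        raise FretDataError(
            f"shape mismatch: IF {IF.shape}, ID {ID.shape}, IA {IA.shape}"
        )
    return IF - delta * ID - alpha * IA


def compute_fret_index(
    cF: np.ndarray,
    qD: np.ndarray,
    QD: float,
    phi_ratio: float,
) -> tuple[np.ndarray, np.ndarray]:
    """FRET index ``F = g*cF / (qD + g*cF)`` with ``g = QD*phi_ratio``.

    Returns ``(F, index_valid)``.  Pixels with ``qD <= 0`` or with a
    non-positive denominator are marked invalid and set to NaN rather than
    propagating division warnings.
    """
    cF = np.asarray(cF, dtype=np.float64)
    qD = np.asarray(qD, dtype=np.float64)
    if cF.shape != qD.shape:
        raise FretDataError(f"shape mismatch: cF {cF.shape}, qD {qD.shape}")
    num = cF * (QD * phi_ratio)
    den = qD + num
    valid = (qD > 0) & (den > 0)
    F = np.full(cF.shape, np.nan)
    np.divide(num, den, out=F, where=valid)
    return F, valid


def median_filter_3x3(F: np.ndarray) -> np.ndarray:
    """3x3 sliding-window median with reflect padding at the borders.

    Applied per frame; idempotent on constant images.  NaN entries (invalid
    pixels) are ignored within each window, so an isolated invalid pixel
    does not poison its neighbourhood; a window of only NaNs stays NaN.
    """
    F = np.asarray(F, dtype=np.float64)
    if F.ndim == 2:
        return _nanmedian3(F)
    return np.stack([_nanmedian3(f) for f in F])


def _nanmedian3(img: np.ndarray) -> np.ndarray:
    pad = np.pad(img, 1, mode="reflect")
    h, w = img.shape
    windows = np.empty((9, h, w))
    k = 0
    for di in range(3):
        for dj in range(3):
            windows[k] = pad[di : di + h, dj : dj + w]
            k += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        return np.nanmedian(windows, axis=0)


def propagate_uncertainty(
    stack: ChannelStack,
    calib: CalibrationParams,
    noise_gain: float | None = None,
) -> np.ndarray:
    """First-order shot-noise propagation through cF and the index.

    With ``N = g*cF`` and denominator ``D = qD + N``:

        dF/dcF =  g*qD / D**2          dF/dqD = -N / D**2
        dF/dIF =  dF/dcF
        dF/dID = -delta*dF/dcF + dF/dqD
        dF/dIA = -alpha*dF/dcF

    and ``sigmaF**2 = sum_c (dF/dI_c)**2 * gain * I_c`` over the three raw
    channels (backgrounds included in the variance, as photons hitting the
    detector).  Pixels where the index is undefined get NaN.
    """
    gain = calib.noise_gain if noise_gain is None else float(noise_gain)
    if gain <= 0:
        raise FretDataError("noise gain must be positive")
    bg = stack.require_background()
    g = calib.gain_factor
    qD = stack.ID - bg["ID"]
    cF = correct_bleedthrough(
        stack.IF - bg["IF"], qD, stack.IA - bg["IA"], calib.alpha, calib.delta
    )
    N = g * cF
    D = qD + N
    valid = (qD > 0) & (D > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_cF = g * qD / D**2
        d_qD = -N / D**2
    p_IF = d_cF
    p_ID = -calib.delta * d_cF + d_qD
    p_IA = -calib.alpha * d_cF
    var = (
        p_IF**2 * gain * np.clip(stack.IF, 0, None)
        + p_ID**2 * gain * np.clip(stack.ID, 0, None)
        + p_IA**2 * gain * np.clip(stack.IA, 0, None)
    )
    sigma = np.full(var.shape, np.nan)
    np.sqrt(var, out=sigma, where=valid)
    return sigma


def threshold_pixels(
    stack: ChannelStack,
    calib: CalibrationParams,
) -> np.ndarray:
    """Validity mask: every raw channel above its ``bg + k*SD(bg)``.

    The background SD follows the shot-noise model,
    ``SD = sqrt(noise_gain * background)``.  An intramolecular sensor is
    bright in all three acquisition channels wherever it is present, so a
    pixel must clear background in each of them; requiring the coincidence
    suppresses isolated shot-noise false positives that a single-channel
    rule lets through at the ~per-cent level.  Because the sensor
    concentrates at cell cortices, the mask also selects sensor-rich
    domains.  An empty mask triggers a warning; downstream ROI operations
    refuse empty selections.
    """
    bg = stack.require_background()
    mask = np.ones(stack.IA.shape, dtype=bool)
    for c in CHANNEL_ORDER:
        sd = float(np.sqrt(calib.noise_gain * max(bg[c], 0.0)))
        mask &= stack.channel(c) > bg[c] + calib.threshold_k * sd
    if not mask.any():
        warnings.warn("intensity threshold produced an empty mask", stacklevel=2)
    return mask


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def compute_fret_map(
    stack: ChannelStack,
    calib: CalibrationParams,
    bin_factor: int | None = None,
    apply_median: bool = True,
) -> FretMap:
    """Run the full index pipeline on a raw stack.

    Order of operations: bin once -> background subtraction -> bleed-through
    correction -> FRET index -> 3x3 median filter -> intensity threshold.
    Binning by ``b`` averages ``b**2`` independent pixels, so the variance
    model applied to binned channels uses an effective gain ``gain / b**2``.
    """
    b = calib.bin_factor if bin_factor is None else int(bin_factor)
    binned = bin_stack(stack, b) if b > 1 else stack
    eff_gain = calib.noise_gain / (b * b)
    sub = subtract_background(binned)
    cF = correct_bleedthrough(sub.IF, sub.ID, sub.IA, calib.alpha, calib.delta)
    qD = sub.ID
    F, index_valid = compute_fret_index(cF, qD, calib.QD, calib.phi_ratio)
    if apply_median:
        F = median_filter_3x3(F)
    sigma = propagate_uncertainty(binned, calib, noise_gain=eff_gain)
    thresh = threshold_pixels(
        binned,
        replace(calib, noise_gain=eff_gain),
    )
    valid = thresh & index_valid & np.isfinite(F)
    return FretMap(F=F, sigmaF=sigma, valid_mask=valid, qD=qD, cF=cF)
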