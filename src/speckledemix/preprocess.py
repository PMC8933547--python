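"""Frame-stack preparation: cropping and Fourier Gaussian high-pass.

The raw frames ride on a smooth fluorescent background; a Gaussian
high-pass in the Fourier domain (spectrum multiplied by ``1 - G``)
removes it while leaving the speckle grains intact.  Filtering can
produce small negative excursions, which must be removed before NMF.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .simulate import FrameStack

__all__ = ["PreprocessConfig", "crop_stack", "highpass_filter", "preprocess_stack"]


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """crop_box is (row0, col0, height, width), 0-based half-open; ``None``
    keeps the full frame.  highpass_sigma is the Gaussian cutoff in cycles
    per frame.  clip_mode: 'clip_zero' zeroes negatives, 'shift_min'
    subtracts the per-frame minimum."""

    crop_box: tuple[int, int, int, int] | None = None
    highpass_sigma: float = 2.0
    clip_mode: str = "clip_zero"

    def __post_init__(self) -> None:
        if self.highpass_sigma <= 0:
            raise ValueError("highpass_sigma must be positive")
        if self.clip_mode not in ("clip_zero", "shift_min"):
            raise ValueError("clip_mode must be 'clip_zero' or 'shift_min'")
        if self.crop_box is not None:
            r0, c0, h, w = self.crop_box
            if h < 1 or w < 1 or r0 < 0 or c0 < 0:
                raise ValueError("invalid crop_box")


def crop_stack(
    stack: FrameStack, crop_box: tuple[int, int, int, int]
) -> FrameStack:
    """Extract the sub-array (row0:row0+h, col0:col0+w) from every frame.

    Pure slicing — no resampling.  Raises if the box leaves the frame.
    """
    r0, c0, h, w = crop_box
    H, W = stack.frame_shape
    if r0 < 0 or c0 < 0 or h < 1 or w < 1 or r0 + h > H or c0 + w > W:
        raise ValueError(f"crop_box {crop_box} exceeds frame bounds {(H, W)}")
    return FrameStack(frames=stack.frames[:, r0 : r0 + h, c0 : c0 + w].copy())


def _highpass_transfer(shape: tuple[int, int], sigma: float) -> np.ndarray:
    """1 - Gaussian(f; sigma) on the FFT frequency grid, sigma in cycles/frame."""
    fr = np.fft.fftfreq(shape[0])[:, None] * shape[0]
    fc = np.fft.fftfreq(shape[1])[None, :] * shape[1]
    return 1.0 - np.exp(-(fr**2 + fc**2) / (2.0 * sigma**2))


def highpass_filter(
    stack: FrameStack,
    highpass_sigma: float,
    clip_mode: str = "clip_zero",
) -> FrameStack:
    """Remove the smooth background: per-frame ``f - G_sigma * f`` via FFT.

    The DC component of every filtered frame is exactly zero before the
    non-negativity step.  Boundary handling is circular (the filter scale
    is far below the frame size, so wrap-around bias is negligible).
    """
    if highpass_sigma <= 0:
        raise ValueError("highpass_sigma must be positive")
    if not np.all(np.isfinite(stack.frames)):
        raise ValueError("stack contains non-finite values")
    transfer = _highpass_transfer(stack.frame_shape, highpass_sigma)
    spectra = np.fft.fft2(stack.frames, axes=(1, 2))
    filtered = np.fft.ifft2(spectra * transfer[None, :, :], axes=(1, 2)).real
    if clip_mode == "clip_zero":
        filtered = np.clip(filtered, 0.0, None)
    elif clip_mode == "shift_min":
        filtered = filtered - filtered.min(axis=(1, 2), keepdims=True)
    else:
        raise ValueError("clip_mode must be 'clip_zero' or 'shift_min'")
    return FrameStack(frames=filtered)


def highpass_filter_raw(
    frames: np.ndarray, highpass_sigma: float
) -> np.ndarray:
    """High-pass without the non-negativity step (used for linearity tests)."""
    transfer = _highpass_transfer(frames.shape[1:], highpass_sigma)
    return np.fft.ifft2(
        np.fft.fft2(frames, axes=(1, 2)) * transfer[None, :, :], axes=(1, 2)
    ).real


def preprocess_stack(stack: FrameStack, config: PreprocessConfig) -> FrameStack:
    """Crop (optional) then high-pass filter a stack."""
    if config.crop_box is not None:
        stack = crop_stack(stack, config.crop_box)
    return highpass_filter(stack, config.highpass_sigma, config.clip_mode)
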