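"""Gabor-filter model of V1 simple cells feeding the network's retina.

Every retinal location carries a hypercolumn: the rectified outputs of a
bank of Gabor filters spanning all combinations of orientation, phase and
spatial frequency.  The two phases (0 and pi) are sign-flipped copies of one
another, so after rectification they encode the positive and negative parts
of the even filter response — firing rates stay non-negative, as the linear
activation stage downstream requires.

Filtering is same-size convolution with symmetric (mirror) padding — a
uniform image therefore yields exactly zero response everywhere, with no
spurious border edges — and it commutes with image translation away from
the borders; the stimulus generator additionally keeps shapes away from
borders.  This equivariance is what lets any learned invariance be
attributed to the trace rule rather than the front end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

__all__ = ["GaborBankSpec", "GaborBank", "build_gabor_bank", "filter_image",
           "default_bank_spec"]


@dataclass(frozen=True)
class GaborBankSpec:
    """Parameter grids of the filter bank.

    ``n_orientations * len(phases) * len(wavelengths)`` must equal the
    configured channel depth of the retina (32 at the 128-px baseline, 64
    for the doubled retina).  ``bandwidth`` is the half-response spatial
    frequency bandwidth in octaves, which fixes the Gaussian envelope scale
    relative to the wavelength; ``aspect`` is the envelope aspect ratio.
    """

    n_orientations: int = 4
    phases: tuple[float, ...] = (0.0, np.pi)
    wavelengths: tuple[float, ...] = (3.0, 6.0, 12.0, 24.0)
    bandwidth: float = 1.5
    aspect: float = 0.5

    @property
    def n_channels(self) -> int:
        return self.n_orientations * len(self.phases) * len(self.wavelengths)

    @property
    def orientations(self) -> tuple[float, ...]:
        return tuple(k * np.pi / self.n_orientations for k in range(self.n_orientations))


def default_bank_spec(retina_size: int = 128, n_channels: int = 32) -> GaborBankSpec:
    """Bank sized to the retina: wavelengths in geometric progression.

    The 32-channel baseline uses 4 orientations x 2 phases x 4 wavelengths;
    the 64-channel large retina adds orientations (8 x 2 x 4).  Wavelengths
    scale with the retina so stimulus edges occupy the same relative band;
    the longest wavelength stays below the target-semicircle radius so that
    neighbouring hand-relative object positions remain resolvable.
    """
    f = retina_size / 128.0
    wavelengths = tuple(3.0 * f * 2 ** k for k in range(4))
    if n_channels == 32:
        return GaborBankSpec(n_orientations=4, wavelengths=wavelengths)
    if n_channels == 64:
        return GaborBankSpec(n_orientations=8, wavelengths=wavelengths)
    raise ValueError(f"no default parameter grid for {n_channels} channels")


def _sigma_from_bandwidth(wavelength: float, bandwidth: float) -> float:
    # standard half-response bandwidth relation for Gabor envelopes
    k = (2.0 ** bandwidth + 1.0) / (2.0 ** bandwidth - 1.0)
    return wavelength / np.pi * np.sqrt(np.log(2.0) / 2.0) * k


def gabor_kernel(wavelength: float, orientation: float, phase: float,
                 bandwidth: float = 1.5, aspect: float = 0.5) -> np.ndarray:
    """Single zero-mean Gabor kernel.

    The DC component is removed by subtracting an envelope-weighted offset,
    so a uniform image elicits exactly zero response.
    """
    sigma = _sigma_from_bandwidth(wavelength, bandwidth)
    extent = int(np.ceil(3.0 * sigma / min(aspect, 1.0)))
    yy, xx = np.mgrid[-extent:extent + 1, -extent:extent + 1].astype(np.float64)
    xr = xx * np.cos(orientation) + yy * np.sin(orientation)
    yr = -xx * np.sin(orientation) + yy * np.cos(orientation)
    env = np.exp(-(xr ** 2 + (aspect * yr) ** 2) / (2.0 * sigma ** 2))
    k = env * np.cos(2.0 * np.pi * xr / wavelength + phase)
    k -= env * (k.sum() / env.sum())
    return k


@dataclass
class GaborBank:
    """Materialized kernels plus cached frequency-domain transforms."""

    spec: GaborBankSpec
    kernels: list[np.ndarray]
    _fft_cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.kernels)


def build_gabor_bank(spec: GaborBankSpec, expected_channels: int | None = None) -> GaborBank:
    """One kernel per (wavelength, orientation, phase) combination."""
    if expected_channels is not None and spec.n_channels != expected_channels:
        raise ValueError(
            f"bank spec yields {spec.n_channels} channels, retina expects {expected_channels}"
        )
    kernels = [
        gabor_kernel(lam, theta, phase, spec.bandwidth, spec.aspect)
        for lam in spec.wavelengths
        for theta in spec.orientations
        for phase in spec.phases
    ]
    return GaborBank(spec=spec, kernels=kernels)


def _bank_ffts(bank: GaborBank, img_shape: tuple[int, int]):
    key = img_shape
    if key in bank._fft_cache:
        return bank._fft_cache[key]
    h, w = img_shape
    kmax = max(k.shape[0] for k in bank.kernels)
    pad = (kmax - 1) // 2 + 1  # symmetric padding margin
    ph = sp_fft.next_fast_len(h + 2 * pad + kmax - 1)
    pw = sp_fft.next_fast_len(w + 2 * pad + kmax - 1)
    ffts = []
    for k in bank.kernels:
        kh = k.shape[0]
        ffts.append((sp_fft.rfft2(k, (ph, pw)), kh))
    bank._fft_cache[key] = (pad, ph, pw, ffts)
    return bank._fft_cache[key]


def filter_image(image: np.ndarray, bank: GaborBank, retina_size: int | None = None,
                 normalize: bool = True) -> np.ndarray:
    """Filter one image through the bank: H x W x C rectified responses.

    Same-size convolution per kernel with symmetric (mirror) boundary
    padding, negative parts clipped to zero.  With ``normalize`` the whole
    response volume is scaled so its maximum is 1, stabilizing the
    percentile-based sigmoid thresholds across frames (contrast is not a
    variable in these experiments).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("expected a square greyscale image")
    if retina_size is not None and image.shape[0] != retina_size:
        raise ValueError(f"image is {image.shape[0]} px, retina expects {retina_size}")
    h, w = image.shape
    pad, ph, pw, ffts = _bank_ffts(bank, image.shape)
    padded = np.pad(image, pad, mode="symmetric")
    img_f = sp_fft.rfft2(padded, (ph, pw))
    out = np.empty((h, w, len(bank.kernels)), dtype=np.float32)
    for c, (kf, ksize) in enumerate(ffts):
        full = sp_fft.irfft2(img_f * kf, (ph, pw))
        off = pad + (ksize - 1) // 2  # 'same' slice, minus the padding
        resp = full[off:off + h, off:off + w]
        out[:, :, c] = np.maximum(resp, 0.0)
    # suppress FFT round-off dust so zero-DC kernels give exact zeros on
    # constant regions
    scale = float(np.abs(image).max())
    if scale > 0:
        out[out < 1e-9 * scale] = 0.0
    if normalize:
        m = float(out.max())
        if m > 0:
            out /= m
    return out
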