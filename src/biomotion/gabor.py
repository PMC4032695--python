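"""Oriented Gabor wavelet dictionary shared by the form pathway.

Each dictionary entry is a quadrature pair (cosine/sine phase) of
DC-free, unit-norm kernels.  Orientations tile ``[0, pi)`` in ``n``
equal steps; scales form a geometric frequency progression
``omega_i = omega0 / scale_step**(i-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = ["GaborElement", "GaborDictionary", "build_dictionary", "respond"]


@dataclass(frozen=True)
class GaborElement:
    """One quadrature Gabor pair.

    ``orientation`` is the direction of the bar/edge the element responds
    to, in radians, one of ``k*pi/n``.  ``center`` is an optional nominal
    (row, col) placement; dictionary entries are built unplaced.
    """

    orientation: float
    orientation_index: int
    scale_index: int  # 1-based
    frequency: float
    kernel_even: np.ndarray = field(repr=False)
    kernel_odd: np.ndarray = field(repr=False)
    center: tuple[int, int] | None = None

    @property
    def kernel_size(self) -> int:
        return self.kernel_even.shape[0]

    def at(self, row: int, col: int) -> "GaborElement":
        """Return a copy placed at a nominal (row, col) center."""
        return replace(self, center=(int(row), int(col)))


@dataclass
class GaborDictionary:
    n_orientations: int
    n_scales: int
    base_size: int
    omega0: float
    scale_step: float
    gamma: float
    sigma_factor: float
    elements: list[GaborElement]

    @property
    def orientations(self) -> np.ndarray:
        return np.arange(self.n_orientations) * np.pi / self.n_orientations

    def element(self, scale_index: int, orientation_index: int) -> GaborElement:
        """Look up an element (scale_index 1-based, orientation_index 0-based)."""
        return self.elements[(scale_index - 1) * self.n_orientations + orientation_index]

    def kernel_size(self, scale_index: int) -> int:
        return self.element(scale_index, 0).kernel_size


def _odd(x: float) -> int:
    n = int(round(x))
    return n if n % 2 == 1 else n + 1


def _gabor_pair(size: int, theta: float, freq: float, gamma: float,
                sigma_factor: float) -> tuple[np.ndarray, np.ndarray]:
    """Build a DC-free, l2-normalized quadrature pair.

    The carrier runs normal to the orientation, so a bar drawn along
    ``theta`` maximizes the even response.
    """
    half = size // 2
    rows, cols = np.mgrid[-half:half + 1, -half:half + 1]
    x, y = cols.astype(float), rows.astype(float)
    along = x * np.cos(theta) + y * np.sin(theta)
    normal = -x * np.sin(theta) + y * np.cos(theta)
    wavelength = 2.0 * np.pi / freq
    sigma = sigma_factor * wavelength
    envelope = np.exp(-((gamma * along) ** 2 + normal ** 2) / (2.0 * sigma ** 2))
    even = envelope * np.cos(freq * normal)
    odd = envelope * np.sin(freq * normal)
    even -= even.mean()
    odd -= odd.mean()
    even /= np.linalg.norm(even)
    odd /= np.linalg.norm(odd)
    return even, odd


def build_dictionary(n_orientations: int = 8, n_scales: int = 2,
                     base_size: int = 17, omega0: float | None = None,
                     scale_step: float = float(np.sqrt(2.0)),
                     gamma: float = 0.5,
                     sigma_factor: float = 0.5) -> GaborDictionary:
    """Construct the oriented multi-scale wavelet dictionary.

    Parameters
    ----------
    n_orientations, n_scales
        Grid of directions (``k*pi/n``) and scales.
    base_size
        Odd kernel side length at the finest scale; coarser scales grow
        proportionally to wavelength.
    omega0
        Carrier frequency at the finest scale. Defaults to a wavelength of
        ``(base_size + 1) / 2`` pixels so the support holds ~2 cycles.
    """
    if n_orientations < 1 or n_scales < 1:
        raise ValueError("n_orientations and n_scales must be >= 1")
    if base_size < 5 or base_size % 2 == 0:
        raise ValueError(f"base_size must be odd and >= 5, got {base_size}")
    if omega0 is None:
        omega0 = 2.0 * np.pi / ((base_size + 1) / 2.0)
    elements: list[GaborElement] = []
    for si in range(1, n_scales + 1):
        freq = omega0 / scale_step ** (si - 1)
        size = _odd(base_size * scale_step ** (si - 1))
        for oi in range(n_orientations):
            theta = oi * np.pi / n_orientations
            even, odd = _gabor_pair(size, theta, freq, gamma, sigma_factor)
            elements.append(GaborElement(
                orientation=theta, orientation_index=oi, scale_index=si,
                frequency=freq, kernel_even=even, kernel_odd=odd))
    return GaborDictionary(
        n_orientations=n_orientations, n_scales=n_scales, base_size=base_size,
        omega0=omega0, scale_step=scale_step, gamma=gamma,
        sigma_factor=sigma_factor, elements=elements)


def respond(frame: np.ndarray, element: GaborElement) -> np.ndarray:
    """Quadrature magnitude response of ``frame`` to one element.

    Zero-padded correlation at every pixel, cropped back to the frame
    lattice; returns ``sqrt(<I,k_even>^2 + <I,k_odd>^2)`` per position.
    The frame mean is removed first so the response is exactly invariant
    to constant offsets even where the zero padding truncates the kernel.
    """
    frame = np.asarray(frame, dtype=float)
    frame = frame - frame.mean()
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D array")
    k = element.kernel_size
    if frame.shape[0] < k or frame.shape[1] < k:
        raise ValueError(
            f"frame {frame.shape} smaller than kernel ({k}x{k})")
    # correlation == convolution with flipped kernel; 'same' zero-pads + crops
    even = fftconvolve(frame, element.kernel_even[::-1, ::-1], mode="same")
    odd = fftconvolve(frame, element.kernel_odd[::-1, ::-1], mode="same")
    return np.hypot(even, odd)
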