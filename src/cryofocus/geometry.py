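"""Euler-angle geometry, the contrast transfer function, and radial Fourier filters.

Conventions
-----------
Orientations follow the ZYZ Euler convention of single-particle metadata:
``R = Rz(psi) @ Ry(tilt) @ Rz(rot)`` with angles in degrees.  The projection
direction of a particle is the rotated z-axis.

The CTF is the standard weak-phase-object model.  Its sign is fixed so that
``CTF(0) = -Q`` (Q the amplitude contrast): protein density projected and
CTF-multiplied gives dark contrast.  Simulator, subtractor and classifier all
share this one convention, which is what makes projection subtraction
self-consistent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

__all__ = [
    "euler_to_matrix",
    "matrix_to_euler",
    "electron_wavelength",
    "CTFParams",
    "ctf_image",
    "RadialFilter",
    "make_lowpass",
    "apply_radial_filter",
    "sharpen",
]


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Rotation matrix ``Rz(psi) @ Ry(tilt) @ Rz(rot)`` from degrees.

    Angles act on (x, y, z) coordinate vectors; the particle viewing
    direction is ``R.T @ [0, 0, 1]``.
    """
    angles = np.asarray([rot, tilt, psi], dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("Euler angles must be finite")
    # extrinsic zyz: from_euler('zyz', [a, b, c]) = Rz(c) @ Ry(b) @ Rz(a)
    return _Rotation.from_euler("zyz", angles, degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; tilt returned in [0, 180]."""
    rot, tilt, psi = _Rotation.from_matrix(np.asarray(matrix, dtype=float)).as_euler(
        "zyz", degrees=True
    )
    return float(rot), float(tilt), float(psi)


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in kV."""
    if voltage_kv <= 0:
        raise ValueError("voltage must be positive")
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v * (1.0 + v * 0.97845e-6))


@dataclass(frozen=True)
class CTFParams:
    """Microscope and defocus parameters of one particle's CTF.

    Defoci are in Angstrom, underfocus positive.  ``amplitude_contrast`` is
    the dimensionless Q in [0, 1); ``astig_angle`` and ``phase_shift`` are in
    degrees.
    """

    voltage: float = 300.0  # kV
    cs: float = 2.7  # mm
    amplitude_contrast: float = 0.1
    defocus_u: float = 10000.0
    defocus_v: float = 10000.0
    astig_angle: float = 0.0
    phase_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if not (0.0 <= self.amplitude_contrast < 1.0):
            raise ValueError("amplitude contrast must be in [0, 1)")
        if not (np.isfinite(self.defocus_u) and np.isfinite(self.defocus_v)):
            raise ValueError("defoci must be finite")

    def evaluate(self, fx: np.ndarray, fy: np.ndarray) -> np.ndarray:
        """CTF gain at spatial frequencies (fx, fy) in 1/Angstrom.

        ``CTF(f) = -[sqrt(1-Q^2) sin(gamma) + Q cos(gamma)]`` with
        ``gamma = pi lambda dz(theta) |f|^2 - (pi/2) Cs lambda^3 |f|^4 + phase``.
        """
        fx = np.asarray(fx, dtype=float)
        fy = np.asarray(fy, dtype=float)
        lam = electron_wavelength(self.voltage)
        f2 = fx * fx + fy * fy
        theta = np.arctan2(fy, fx)
        dz_mid = 0.5 * (self.defocus_u + self.defocus_v)
        dz_dif = 0.5 * (self.defocus_u - self.defocus_v)
        dz = dz_mid + dz_dif * np.cos(2.0 * (theta - np.deg2rad(self.astig_angle)))
        cs_a = self.cs * 1e7  # mm -> Angstrom
        gamma = (
            np.pi * lam * dz * f2
            - 0.5 * np.pi * cs_a * lam**3 * f2 * f2
            + np.deg2rad(self.phase_shift)
        )
        q = self.amplitude_contrast
        return -(np.sqrt(1.0 - q * q) * np.sin(gamma) + q * np.cos(gamma))


def ctf_image(ctf: CTFParams, box: int, pixel_size: float) -> np.ndarray:
    """Sample the CTF on the FFT frequency grid of a ``box``-pixel image.

    Returned in np.fft ordering (DC at [0, 0]) so it can multiply ``fft2``
    output directly.
    """
    freqs = np.fft.fftfreq(box, d=pixel_size)
    fy = freqs[:, None]
    fx = freqs[None, :]
    return ctf.evaluate(fx, fy)


class RadialFilter:
    """A radial Fourier gain tabulated against spatial frequency (1/Angstrom).

    Linearly interpolated between table points; clamped to the edge values
    outside the tabulated range.  Used for low-pass filters and detector MTF
    curves alike.
    """

    def __init__(self, freqs: np.ndarray, gains: np.ndarray):
        freqs = np.asarray(freqs, dtype=float)
        gains = np.asarray(gains, dtype=float)
        if freqs.ndim != 1 or freqs.shape != gains.shape:
            raise ValueError("freqs and gains must be matching 1-D arrays")
        if freqs[0] != 0.0 or np.any(np.diff(freqs) <= 0):
            raise ValueError("frequency grid must increase strictly from 0")
        if not np.all(np.isfinite(gains)):
            raise ValueError("gains must be finite")
        self.freqs = freqs
        self.gains = gains

    def __call__(self, nu: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(nu, dtype=float), self.freqs, self.gains)

    @classmethod
    def from_table(cls, path) -> "RadialFilter":
        """Load a two-column text table (frequency 1/A, gain), e.g. an MTF curve."""
        table = np.loadtxt(path)
        if table.ndim != 2 or table.shape[1] < 2:
            raise ValueError("expected a two-column table")
        return cls(table[:, 0], table[:, 1])

    def to_table(self, path) -> None:
        np.savetxt(path, np.column_stack([self.freqs, self.gains]))


def make_lowpass(cutoff_resolution: float, box: int, pixel_size: float) -> RadialFilter:
    """Cosine-edged low-pass filter at ``cutoff_resolution`` Angstrom.

    Gain is 1 up to the cutoff frequency and falls along a cosine half-cycle
    to exactly 0 over the next 2 reciprocal pixels (1 reciprocal pixel =
    1/(box * pixel_size)).  Cutoffs beyond Nyquist clamp to an all-pass.
    """
    if cutoff_resolution <= 0:
        raise ValueError("cutoff resolution must be positive")
    nu_c = 1.0 / cutoff_resolution
    rec_px = 1.0 / (box * pixel_size)
    nyquist = 0.5 / pixel_size
    nu_max = nyquist + 2.0 * rec_px
    if nu_c >= nyquist:
        return RadialFilter(np.array([0.0, nu_max]), np.array([1.0, 1.0]))
    # tabulate the cosine edge finely; the midpoint and endpoints are exact
    edge = nu_c + 2.0 * rec_px * np.linspace(0.0, 1.0, 65)
    gain_edge = 0.5 * (1.0 + np.cos(np.pi * np.linspace(0.0, 1.0, 65)))
    freqs = np.concatenate([[0.0], edge, [max(nu_max, edge[-1] + rec_px)]])
    gains = np.concatenate([[1.0], gain_edge, [0.0]])
    return RadialFilter(freqs, gains)


def _radial_frequency_grid(shape: tuple[int, ...], pixel_size: float) -> np.ndarray:
    axes = [np.fft.fftfreq(n, d=pixel_size) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(g * g for g in grids))


def apply_radial_filter(volume_or_image, filt: RadialFilter, mode: str = "multiply"):
    """Scale Fourier amplitudes shell-wise by a radial filter.

    Accepts a bare ndarray together with objects exposing ``.data`` and
    ``.pixel_size`` (VolumeGrid, ParticleImage); returns the same type.
    ``mode='divide'`` (e.g. MTF correction) requires strictly positive gains
    over the sampled frequency support.
    """
    if mode not in ("multiply", "divide"):
        raise ValueError("mode must be 'multiply' or 'divide'")
    obj = volume_or_image
    wrapped = hasattr(obj, "data") and hasattr(obj, "pixel_size")
    data = np.asarray(obj.data if wrapped else obj, dtype=float)
    pixel_size = obj.pixel_size if wrapped else 1.0
    nu = _radial_frequency_grid(data.shape, pixel_size)
    gain = filt(nu)
    if mode == "divide":
        if np.any(gain <= 0):
            raise ZeroDivisionError("divide mode requires positive gains on the support")
        gain = 1.0 / gain
    out = np.fft.ifftn(np.fft.fftn(data) * gain).real
    if wrapped:
        return dataclasses.replace(obj, data=out)
    return out


def sharpen(volume, b_factor: float, lowpass: float | None = None):
    """B-factor sharpening: scale amplitudes by ``exp(-B nu^2 / 4)``.

    Negative ``b_factor`` sharpens (the usual case, e.g. -100 A^2), positive
    blurs.  An optional cosine low-pass at ``lowpass`` Angstrom is applied
    afterwards to suppress the amplified high-frequency noise.
    """
    wrapped = hasattr(volume, "data") and hasattr(volume, "pixel_size")
    data = np.asarray(volume.data if wrapped else volume, dtype=float)
    pixel_size = volume.pixel_size if wrapped else 1.0
    nu = _radial_frequency_grid(data.shape, pixel_size)
    out = np.fft.ifftn(np.fft.fftn(data) * np.exp(-b_factor * nu * nu / 4.0)).real
    if wrapped:
        out_obj = dataclasses.replace(volume, data=out)
    else:
        out_obj = out
    if lowpass is not None:
        filt = make_lowpass(lowpass, data.shape[0], pixel_size)
        out_obj = apply_radial_filter(out_obj, filt, "multiply")
    return out_obj
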