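"""Forward projection and direct Fourier reconstruction.

The projector implements the Fourier-slice theorem: the 2D transform of a
projection is a central plane of the 3D transform.  Volumes are oversampled
(default pad factor 2), slices are extracted with trilinear interpolation,
and the interpolation blur is compensated by a sinc^2 gridding correction in
real space.  Orientations that are signed axis permutations (identity, 90
degree views) land exactly on grid planes, where interpolation is exact and
the gridding correction would bias the result; those take an exact
permute-and-sum path instead.

Translational offsets are applied as Fourier phase shifts on the projection
(the reference is shifted toward the particle); simulator, subtractor and
classifier all go through this one projector, so the convention is shared.
"""

from __future__ import annotations

import numpy as np

from .geometry import CTFParams
from .io_formats import ParticleImage, VolumeGrid

__all__ = [
    "FourierVolume",
    "ReconstructionAccumulator",
    "project",
    "backproject_accumulate",
    "backproject_volume",
    "reconstruct",
]


# centered FFT helpers: arrays carry DC at index n//2 in every axis
def fft2_c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(a)))


def ifft2_c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(a)))


def fftn_c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a)))


def ifftn_c(a: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(a)))


def gridding_correction(box: int, pad_factor: int) -> np.ndarray:
    """Separable sinc^2 correction for trilinear interpolation at pad p."""
    r = np.arange(box) - box // 2
    c1 = np.sinc(r / (pad_factor * box)) ** 2
    return c1[:, None, None] * c1[None, :, None] * c1[None, None, :]


def _signed_permutation(r: np.ndarray, tol: float = 1e-10) -> np.ndarray | None:
    """Return the integer matrix if ``r`` is a signed permutation, else None."""
    ri = np.round(r)
    if np.max(np.abs(r - ri)) > tol:
        return None
    if not np.array_equal(np.sort(np.abs(ri), axis=None)[-3:], [1, 1, 1]):
        return None
    if np.abs(np.abs(ri).sum(axis=0) - 1).max() or np.abs(np.abs(ri).sum(axis=1) - 1).max():
        return None
    return ri.astype(int)


def trilinear_weights(
    coords: np.ndarray, shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices and weights of the 8 trilinear neighbours of each point.

    ``coords`` is (M, 3) in (z, y, x) index space.  Out-of-range neighbours
    get weight 0 and are redirected to index 0.
    """
    f = np.floor(coords)
    t = coords - f
    f = f.astype(np.int64)
    nz, ny, nx = shape
    idx8 = np.empty((coords.shape[0], 8), dtype=np.int64)
    w8 = np.empty((coords.shape[0], 8), dtype=np.float64)
    k = 0
    for dz in (0, 1):
        wz = t[:, 0] if dz else 1.0 - t[:, 0]
        z = f[:, 0] + dz
        for dy in (0, 1):
            wy = t[:, 1] if dy else 1.0 - t[:, 1]
            y = f[:, 1] + dy
            for dx in (0, 1):
                wx = t[:, 2] if dx else 1.0 - t[:, 2]
                x = f[:, 2] + dx
                inside = (
                    (z >= 0) & (z < nz) & (y >= 0) & (y < ny) & (x >= 0) & (x < nx)
                )
                flat = np.where(inside, (z * ny + y) * nx + x, 0)
                idx8[:, k] = flat
                w8[:, k] = np.where(inside, wz * wy * wx, 0.0)
                k += 1
    return idx8, w8


class FourierVolume:
    """Oversampled centered Fourier transform of a volume, ready for slicing."""

    def __init__(self, vol: VolumeGrid, pad_factor: int = 2):
        if pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        self.box = vol.box
        self.pad_factor = pad_factor
        self.pixel_size = vol.pixel_size
        self.volume_data = vol.data
        n, p = self.box, pad_factor
        corrected = vol.data / gridding_correction(n, p)
        padded = np.zeros((p * n,) * 3)
        lo = (p * n - n) // 2
        padded[lo : lo + n, lo : lo + n, lo : lo + n] = corrected
        self.transform = fftn_c(padded)
        self.center = (p * n) // 2

    def slice_coords(self, r: np.ndarray) -> np.ndarray:
        """Padded-grid (z, y, x) coordinates of the centered image-frequency plane."""
        n, p = self.box, self.pad_factor
        h = np.arange(n) - n // 2
        hx, hy = np.meshgrid(h, h, indexing="xy")  # image FT row = y-freq
        pts = np.stack([hx.ravel(), hy.ravel(), np.zeros(n * n)], axis=1)
        q = pts @ r  # row-vector form of q = R^T @ (h, k, 0)
        coords = np.empty_like(q)
        coords[:, 0] = p * q[:, 2] + self.center
        coords[:, 1] = p * q[:, 1] + self.center
        coords[:, 2] = p * q[:, 0] + self.center
        return coords

    def extract_slice(self, r: np.ndarray) -> np.ndarray:
        """Centered 2D Fourier slice at rotation ``r`` (trilinear gather)."""
        coords = self.slice_coords(r)
        idx8, w8 = trilinear_weights(coords, self.transform.shape)
        flat = self.transform.ravel()
        vals = (flat[idx8] * w8).sum(axis=1)
        return vals.reshape(self.box, self.box)


def _phase_ramp(box: int, origin_x: float, origin_y: float) -> np.ndarray:
    h = np.arange(box) - box // 2
    px = np.exp(-2j * np.pi * origin_x * h / box)
    py = np.exp(-2j * np.pi * origin_y * h / box)
    return py[:, None] * px[None, :]


def _ctf_centered(ctf: CTFParams, box: int, pixel_size: float) -> np.ndarray:
    h = (np.arange(box) - box // 2) / (box * pixel_size)
    return ctf.evaluate(h[None, :], h[:, None])


def _aligned_projection(data: np.ndarray, ri: np.ndarray) -> np.ndarray:
    """Exact projection for signed-permutation rotations by permute-and-sum.

    The rotated volume is ``V'(x) = V(R^T x)`` about the center voxel; index
    wrap-around follows the periodic (DFT) convention, matching the Fourier
    path exactly on these orientations.
    """
    n = data.shape[0]
    c = n // 2
    g = np.arange(n) - c
    ox = g[None, None, :]
    oy = g[None, :, None]
    oz = g[:, None, None]
    rt = ri.T
    xin = rt[0, 0] * ox + rt[0, 1] * oy + rt[0, 2] * oz
    yin = rt[1, 0] * ox + rt[1, 1] * oy + rt[1, 2] * oz
    zin = rt[2, 0] * ox + rt[2, 1] * oy + rt[2, 2] * oz
    rotated = data[(zin + c) % n, (yin + c) % n, (xin + c) % n]
    return rotated.sum(axis=0)


def project(
    vol: VolumeGrid | FourierVolume,
    r: np.ndarray,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
    ctf: CTFParams | None = None,
    pad_factor: int = 2,
) -> ParticleImage:
    """Project a volume at rotation ``r`` with offsets and optional CTF.

    ``r`` is the particle rotation matrix from :func:`euler_to_matrix`; the
    projection direction is the rotated z-axis.  Offsets shift the projection
    toward the particle (in pixels) via Fourier phase ramps.
    """
    fv = vol if isinstance(vol, FourierVolume) else FourierVolume(vol, pad_factor)
    n = fv.box
    if abs(origin_x) >= n / 4 or abs(origin_y) >= n / 4:
        raise ValueError("offsets must satisfy |o| < box/4")
    ri = _signed_permutation(np.asarray(r, dtype=float))
    if ri is not None:
        image = _aligned_projection(fv.volume_data, ri)
        if origin_x == 0.0 and origin_y == 0.0 and ctf is None:
            return ParticleImage(image, fv.pixel_size)
        g = fft2_c(image)
    else:
        g = fv.extract_slice(np.asarray(r, dtype=float))
    if origin_x != 0.0 or origin_y != 0.0:
        g = g * _phase_ramp(n, origin_x, origin_y)
    if ctf is not None:
        g = g * _ctf_centered(ctf, n, fv.pixel_size)
    return ParticleImage(ifft2_c(g).real, fv.pixel_size)


class ReconstructionAccumulator:
    """Numerator/denominator grids of a direct Fourier reconstruction.

    Each oriented image adds ``weight * CTF * FT(image)`` into the numerator
    and ``weight * CTF^2`` into the denominator along its central plane,
    spread with the same trilinear weights the projector gathers with.
    """

    def __init__(self, box: int, pixel_size: float, pad_factor: int = 2):
        self.box = box
        self.pixel_size = pixel_size
        self.pad_factor = pad_factor
        m = pad_factor * box
        self.num = np.zeros((m, m, m), dtype=np.complex128)
        self.den = np.zeros((m, m, m), dtype=np.float64)
        self.center = m // 2
        self.weight_total = 0.0
        h = np.arange(box) - box // 2
        hx, hy = np.meshgrid(h, h, indexing="xy")
        self._plane = np.stack([hx.ravel(), hy.ravel(), np.zeros(box * box)], axis=1)

    def coords(self, r: np.ndarray) -> np.ndarray:
        q = self._plane @ np.asarray(r, dtype=float)
        coords = np.empty_like(q)
        coords[:, 0] = self.pad_factor * q[:, 2] + self.center
        coords[:, 1] = self.pad_factor * q[:, 1] + self.center
        coords[:, 2] = self.pad_factor * q[:, 0] + self.center
        return coords

    def add_image(
        self,
        image: ParticleImage,
        r: np.ndarray,
        origin_x: float = 0.0,
        origin_y: float = 0.0,
        ctf: CTFParams | None = None,
        weight: float = 1.0,
    ) -> None:
        if not np.isfinite(weight):
            raise ValueError("weight must be finite")
        if image.box != self.box:
            raise ValueError("image box does not match accumulator")
        if weight == 0.0:
            return
        g = fft2_c(image.data)
        if origin_x != 0.0 or origin_y != 0.0:
            g = g * np.conj(_phase_ramp(self.box, origin_x, origin_y))
        if ctf is not None:
            c = _ctf_centered(ctf, self.box, self.pixel_size)
        else:
            c = np.ones((self.box, self.box))
        idx8, w8 = trilinear_weights(self.coords(r), self.den.shape)
        num_vals = (weight * c * g).ravel()
        den_vals = (weight * c * c).ravel()
        np.add.at(self.num.ravel(), idx8, w8 * num_vals[:, None])
        np.add.at(self.den.ravel(), idx8, w8 * den_vals[:, None])
        self.weight_total += weight

    def finish(self, epsilon: float | None = None) -> VolumeGrid:
        """Wiener-style division, inverse transform, crop, gridding correction."""
        if self.weight_total <= 0.0:
            raise ValueError("no data accumulated (all-zero weights)")
        nz = self.den > 0
        if epsilon is None:
            epsilon = 1e-3 * float(self.den[nz].mean()) if nz.any() else 1e-3
        ratio = self.num / (self.den + epsilon)
        full = ifftn_c(ratio).real
        n = self.box
        lo = (self.pad_factor * n - n) // 2
        cropped = full[lo : lo + n, lo : lo + n, lo : lo + n]
        return VolumeGrid(cropped / gridding_correction(n, self.pad_factor), self.pixel_size)


def backproject_accumulate(
    acc: ReconstructionAccumulator,
    image: ParticleImage,
    r: np.ndarray,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
    ctf: CTFParams | None = None,
    weight: float = 1.0,
) -> ReconstructionAccumulator:
    """Add one oriented image into a reconstruction accumulator (in place)."""
    acc.add_image(image, r, origin_x, origin_y, ctf, weight)
    return acc


def backproject_volume(
    image: ParticleImage,
    r: np.ndarray,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
    pad_factor: int = 2,
) -> VolumeGrid:
    """The exact adjoint of :func:`project` (general path, no CTF).

    Satisfies ``<project(V), I> = <V, backproject_volume(I)>`` for real V, I.
    """
    n = image.box
    p = pad_factor
    acc = ReconstructionAccumulator(n, image.pixel_size, p)
    g = fft2_c(image.data) / (n * n)
    if origin_x != 0.0 or origin_y != 0.0:
        g = g * np.conj(_phase_ramp(n, origin_x, origin_y))
    idx8, w8 = trilinear_weights(acc.coords(np.asarray(r, dtype=float)), acc.num.shape)
    np.add.at(acc.num.ravel(), idx8, w8 * g.ravel()[:, None])
    m = p * n
    full = ifftn_c(acc.num).real * (m**3)
    lo = (m - n) // 2
    cropped = full[lo : lo + n, lo : lo + n, lo : lo + n]
    return VolumeGrid(cropped / gridding_correction(n, p), image.pixel_size)


def reconstruct(
    particles,
    images: "np.ndarray | list",
    weights=None,
    epsilon: float | None = None,
    pad_factor: int = 2,
    pixel_size: float | None = None,
    use_ctf: bool = True,
) -> VolumeGrid:
    """Direct Fourier reconstruction from oriented, CTF-affected images.

    ``particles`` supplies per-image rotations, offsets and CTFs (a
    ParticleSet); ``images`` is an ImageStack or (n, N, N) array.  ``weights``
    are per-particle responsibilities (default 1).
    """
    from .geometry import euler_to_matrix
    from .io_formats import ImageStack

    if isinstance(images, ImageStack):
        data = images.data
        pixel_size = images.pixel_size
    else:
        data = np.asarray(images, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required for bare arrays")
    n = data.shape[1]
    recs = list(particles)
    if len(recs) != data.shape[0]:
        raise ValueError("particle count does not match image count")
    if weights is None:
        weights = np.ones(len(recs))
    weights = np.asarray(weights, dtype=float)
    if not np.any(weights > 0):
        raise ValueError("all weights are zero")
    acc = ReconstructionAccumulator(n, pixel_size, pad_factor)
    for rec, img, w in zip(recs, data, weights):
        if w == 0.0:
            continue
        acc.add_image(
            ParticleImage(img, pixel_size),
            euler_to_matrix(rec.rot, rec.tilt, rec.psi),
            rec.origin_x,
            rec.origin_y,
            rec.ctf if use_ctf else None,
            w,
        )
    return acc.finish(epsilon)
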