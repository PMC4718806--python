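"""FSC computation, resolution estimation and mask-corrected validation.

Map quality is judged by the Fourier shell correlation (FSC) between two
reconstructions from independent half-sets, with resolution reported at the
FSC = 0.143 threshold.  Because a soft mask correlates the two half-maps
through its own shape, masked FSC curves are corrected by high-resolution
noise substitution: the phases of both half-maps are randomized beyond a
chosen frequency, the spurious masked correlation FSC_n of the randomized
maps is measured, and the true curve is corrected as
``(FSC_t - FSC_n) / (1 - FSC_n)`` beyond that frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import VolumeGrid
from .masks import SoftMask, apply_mask

__all__ = [
    "FSCCurve",
    "compute_fsc",
    "resolution_at",
    "fsc_noise_substitution",
    "split_half_sets",
    "run_report",
]


@dataclass(frozen=True)
class FSCCurve:
    """Shell-wise correlation values against spatial frequency (1/Angstrom)."""

    freqs: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    flags: np.ndarray = field(default=None)  # True where a shell had zero power

    def __post_init__(self) -> None:
        if self.flags is None:
            object.__setattr__(self, "flags", np.zeros(len(self.values), dtype=bool))

    def to_table(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.freqs, self.values]),
            header="frequency(1/A) fsc",
        )

    def plot(self, path, threshold: float = 0.143) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.freqs, self.values)
        ax.axhline(threshold, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("spatial frequency (1/$\\AA$)")
        ax.set_ylabel("FSC")
        ax.set_ylim(-0.1, 1.05)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _shell_indices_3d(box: int) -> np.ndarray:
    f = np.fft.fftfreq(box) * box
    r = np.sqrt(
        f[:, None, None] ** 2 + f[None, :, None] ** 2 + f[None, None, :] ** 2
    )
    return np.round(r).astype(int)


def compute_fsc(
    v1: VolumeGrid, v2: VolumeGrid, mask: SoftMask | None = None
) -> FSCCurve:
    """Shell-wise normalized cross-correlation of two maps' Fourier terms."""
    if v1.box != v2.box or not np.isclose(v1.pixel_size, v2.pixel_size):
        raise ValueError("grid mismatch between maps")
    if mask is not None:
        v1 = apply_mask(v1, mask)
        v2 = apply_mask(v2, mask)
    box = v1.box
    f1 = np.fft.fftn(v1.data)
    f2 = np.fft.fftn(v2.data)
    shells = _shell_indices_3d(box).ravel()
    n_shell = box // 2 + 1
    keep = shells < n_shell
    s = shells[keep]
    cross = np.bincount(s, (f1.ravel()[keep] * np.conj(f2.ravel()[keep])).real, minlength=n_shell)
    p1 = np.bincount(s, np.abs(f1.ravel()[keep]) ** 2, minlength=n_shell)
    p2 = np.bincount(s, np.abs(f2.ravel()[keep]) ** 2, minlength=n_shell)
    counts = np.bincount(s, minlength=n_shell)
    flags = (p1 <= 0) | (p2 <= 0)
    denom = np.sqrt(np.where(flags, 1.0, p1 * p2))
    values = np.where(flags, 0.0, cross / denom)
    freqs = np.arange(n_shell) / (box * v1.pixel_size)
    return FSCCurve(freqs, values, counts, flags)


def resolution_at(curve: FSCCurve, threshold: float = 0.143) -> tuple[float, bool]:
    """Resolution (Angstrom) at the first downward crossing of ``threshold``.

    Linear interpolation between shells.  Returns ``(resolution, crossed)``;
    when the curve never drops below the threshold the Nyquist resolution is
    returned with ``crossed=False``.
    """
    v = curve.values
    if v[0] <= threshold:
        raise ValueError("FSC curve must start above the threshold")
    below = np.flatnonzero(v < threshold)
    if below.size == 0:
        return float(1.0 / curve.freqs[-1]), False
    j = below[0]
    f0, f1 = curve.freqs[j - 1], curve.freqs[j]
    v0, v1 = v[j - 1], v[j]
    f_cross = f0 + (v0 - threshold) / (v0 - v1) * (f1 - f0)
    return float(1.0 / f_cross), True


def _randomize_phases(vol: VolumeGrid, from_shell: int, rng) -> VolumeGrid:
    """Replace phases beyond ``from_shell`` with uniform random phases."""
    box = vol.box
    f = np.fft.fftn(vol.data)
    shells = _shell_indices_3d(box)
    high = shells > from_shell
    # random Hermitian phase field: use the phases of a random real volume
    ph = np.fft.fftn(rng.standard_normal(vol.data.shape))
    ph = ph / np.maximum(np.abs(ph), 1e-300)
    f = np.where(high, np.abs(f) * ph, f)
    return VolumeGrid(np.fft.ifftn(f).real, vol.pixel_size)


def fsc_noise_substitution(
    half1: VolumeGrid,
    half2: VolumeGrid,
    mask: SoftMask,
    randomize_from: float | None = None,
    seed: int = 0,
) -> FSCCurve:
    """Mask-corrected FSC by high-resolution noise substitution.

    ``randomize_from`` is in Angstrom; by default the frequency where the
    unmasked FSC first drops below 0.8.  Shells at or before it are the
    plain masked FSC; beyond it the corrected value
    ``(FSC_t - FSC_n)/(1 - FSC_n)`` is reported, with shells where
    ``FSC_n = 1`` flagged invalid.
    """
    box = half1.box
    if randomize_from is None:
        unmasked = compute_fsc(half1, half2)
        low = np.flatnonzero(unmasked.values < 0.8)
        shell0 = int(low[0]) if low.size else box // 2 - 1
        shell0 = max(shell0, 1)
    else:
        shell0 = int(round(box * half1.pixel_size / randomize_from))
        if shell0 >= box // 2:
            raise ValueError("randomize_from must be coarser than Nyquist")
    rng = np.random.default_rng(seed)
    fsc_t = compute_fsc(half1, half2, mask)
    r1 = _randomize_phases(half1, shell0, rng)
    r2 = _randomize_phases(half2, shell0, rng)
    fsc_n = compute_fsc(r1, r2, mask)
    values = fsc_t.values.copy()
    flags = fsc_t.flags.copy()
    beyond = np.arange(len(values)) > shell0
    bad = beyond & (np.abs(1.0 - fsc_n.values) < 1e-12)
    ok = beyond & ~bad
    values[ok] = (fsc_t.values[ok] - fsc_n.values[ok]) / (1.0 - fsc_n.values[ok])
    flags |= bad
    return FSCCurve(fsc_t.freqs, values, fsc_t.counts, flags)


def split_half_sets(n: int, seed: int = 0) -> np.ndarray:
    """Gold-standard half-set labels (1 or 2) by even/odd of a seeded shuffle."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    labels[order] = np.arange(n) % 2 + 1
    return labels


def run_report(
    model,
    resp: np.ndarray,
    history: list,
    truth_labels=None,
    resolutions: dict | None = None,
    extra: dict | None = None,
) -> dict:
    """Aggregate a classification run into a machine-readable report."""
    if not history:
        raise ValueError("empty classification history")
    resp = np.asarray(resp, dtype=float)
    assigned = resp.argmax(axis=1)
    counts = np.bincount(assigned, minlength=model.n_classes)
    report = {
        "n_particles": int(resp.shape[0]),
        "n_classes": int(model.n_classes),
        "iterations": int(history[-1]["iteration"]),
        "class_fractions": [float(f) for f in model.fractions],
        "class_counts": [int(c) for c in counts],
        "mean_log_evidence": float(history[-1]["mean_log_evidence"]),
    }
    if truth_labels is not None:
        from .simulation import score_classification

        report["accuracy"] = float(score_classification(resp, truth_labels))
    if resolutions:
        report["resolutions_A"] = {str(k): float(v) for k, v in resolutions.items()}
    if extra:
        report.update(extra)
    return report
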