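"""Masked multi-reference maximum-likelihood classification, no alignment.

Particles are classified among K reference volumes with their orientations
and offsets held fixed at consensus-refinement values — the regime where
the region of interest is too small to drive an orientation search.
References are multiplied by the focus mask each iteration, so only the
masked region contributes to the likelihood.  The noise model is a single
shared per-Fourier-shell Gaussian variance, updated by EM along with the
references and class fractions.

Likelihood convention: with normalized image transforms ``D = fft2(d)/N``,

    ln L_ik = - sum_f |D_i(f) - CTF_i(f) S_k(f)|^2 / (2 sigma^2(nu(f)))
              - sum_s m_s ln(2 pi sigma^2(s))

summed over frequencies from shell 1 up to the classification resolution
limit (the DC term is excluded; it measures background, not structure).
``sigma^2`` is the variance of the real and imaginary parts separately and
``m_s`` the number of complex components in shell s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .geometry import apply_radial_filter, euler_to_matrix, make_lowpass
from .io_formats import ImageStack, ParticleSet, VolumeGrid
from .masks import SoftMask, apply_mask
from .projection import (
    FourierVolume,
    gridding_correction,
    ifftn_c,
    trilinear_weights,
)
from .simulation import shell_index_map

__all__ = [
    "NoiseSpectrum",
    "ClassModel",
    "init_classes",
    "e_step",
    "m_step",
    "classify",
    "select_classes",
]


@dataclass(frozen=True)
class NoiseSpectrum:
    """Per-shell variance of the real/imaginary Fourier components."""

    sigma2: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma2, dtype=float)
        object.__setattr__(self, "sigma2", s)
        if np.any(~np.isfinite(s)) or np.any(s <= 0):
            raise ValueError("noise variances must be positive and finite")


@dataclass(frozen=True)
class ClassModel:
    """K masked references with class fractions and a shared noise model."""

    references: tuple[VolumeGrid, ...]
    fractions: np.ndarray
    noise: NoiseSpectrum
    focus_mask: SoftMask | None = None
    iteration: int = 0
    resolution_shell: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "references", tuple(self.references))
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if len(self.references) < 1:
            raise ValueError("need at least one class")
        if len(f) != len(self.references):
            raise ValueError("fractions/references length mismatch")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be >= 0 and sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.references)


class _Engine:
    """Precomputed per-particle Fourier data for fixed-orientation EM.

    Orientations never change during classification, so the Fourier-plane
    selection, slice coordinates and CTF samples of every particle are
    computed once.  E- and M-steps are then batched gathers/scatters against
    each class's oversampled reference transform.
    """

    def __init__(
        self,
        particles: ParticleSet,
        images: ImageStack,
        resolution_shell: int | None = None,
        pad_factor: int = 2,
        batch: int = 256,
    ):
        if len(particles) != len(images):
            raise ValueError("particle count does not match image count")
        n_img = len(images)
        box = images.box
        self.box = box
        self.pixel_size = images.pixel_size
        self.pad = pad_factor
        self.batch = batch
        self.smax = box // 2 - 2 if resolution_shell is None else int(resolution_shell)
        if not (1 <= self.smax <= box // 2):
            raise ValueError("resolution shell out of range")

        shells = shell_index_map(box).ravel()
        sel = np.flatnonzero(shells <= self.smax)
        order = np.argsort(shells[sel], kind="stable")
        self.sel = sel[order]
        self.shell_of_sel = shells[self.sel]
        self.n_shell = self.smax + 1
        self.m_s = np.bincount(self.shell_of_sel, minlength=self.n_shell).astype(float)
        self.bounds = np.searchsorted(self.shell_of_sel, np.arange(self.n_shell))

        # normalized data transforms, phase-referenced to the image center
        # (matching the projector), un-shifted into the reference frame
        d = np.fft.fft2(np.fft.ifftshift(images.data, axes=(1, 2))) / box
        d = d.reshape(n_img, -1)[:, self.sel]
        f = np.fft.fftfreq(box) * box
        hx = np.broadcast_to(f[None, :], (box, box)).ravel()[self.sel]
        hy = np.broadcast_to(f[:, None], (box, box)).ravel()[self.sel]
        ox = np.array([r.origin_x for r in particles])
        oy = np.array([r.origin_y for r in particles])
        if np.any(ox) or np.any(oy):
            ramp = np.exp(
                -2j * np.pi * (ox[:, None] * hx[None, :] + oy[:, None] * hy[None, :]) / box
            )
            d = d * np.conj(ramp)
        self.data = d

        freqs_a = np.stack([hx, hy], axis=1) / (box * self.pixel_size)
        ctfs = np.empty((n_img, self.sel.size), dtype=np.float32)
        m = pad_factor * box
        center = m // 2
        plane = np.stack([hx, hy, np.zeros_like(hx)], axis=1)
        self.grid_shape = (m, m, m)
        self.n_img = n_img
        # orientations are fixed for the whole run, so the trilinear gather
        # pattern of every particle is computed once and cached (int32/float32
        # keeps this ~200 bytes per Fourier component per particle)
        self.idx8 = np.empty((n_img, self.sel.size, 8), dtype=np.int32)
        self.w8 = np.empty((n_img, self.sel.size, 8), dtype=np.float32)
        coords = np.empty((self.sel.size, 3))
        for i, rec in enumerate(particles):
            ctfs[i] = rec.ctf.evaluate(freqs_a[:, 0], freqs_a[:, 1])
            q = plane @ euler_to_matrix(rec.rot, rec.tilt, rec.psi)
            coords[:, 0] = pad_factor * q[:, 2] + center
            coords[:, 1] = pad_factor * q[:, 1] + center
            coords[:, 2] = pad_factor * q[:, 0] + center
            idx, w = trilinear_weights(coords, self.grid_shape)
            self.idx8[i] = idx
            self.w8[i] = w
        self.ctfs = ctfs

    # -- likelihood -------------------------------------------------------

    def _weights(self, noise: NoiseSpectrum, shell_limit: int | None = None) -> np.ndarray:
        w = 1.0 / (2.0 * noise.sigma2[: self.n_shell])
        w[0] = 0.0  # DC excluded
        if shell_limit is not None:
            w[shell_limit + 1 :] = 0.0
        return w

    def residual_shell_sums(self, model: ClassModel) -> np.ndarray:
        """Per-(particle, class, shell) residual power sums."""
        k_classes = model.n_classes
        out = np.empty((self.n_img, k_classes, self.n_shell))
        flats = [
            FourierVolume(ref, self.pad).transform.ravel() / self.box
            for ref in model.references
        ]
        for lo in range(0, self.n_img, self.batch):
            hi = min(lo + self.batch, self.n_img)
            idx8 = self.idx8[lo:hi].reshape(-1, 8)
            w8 = self.w8[lo:hi].reshape(-1, 8)
            for k, flat in enumerate(flats):
                s = flat[idx8[:, 0]] * w8[:, 0]
                for j in range(1, 8):
                    s += flat[idx8[:, j]] * w8[:, j]
                s = s.reshape(hi - lo, -1)
                resid = self.data[lo:hi] - self.ctfs[lo:hi] * s
                p = np.abs(resid) ** 2
                out[lo:hi, k] = np.add.reduceat(p, self.bounds, axis=1)
        return out

    def log_likelihood(
        self,
        shell_sums: np.ndarray,
        noise: NoiseSpectrum,
        shell_limit: int | None = None,
    ) -> np.ndarray:
        """Per-(particle, class) log-likelihood, optionally band-limited."""
        w = self._weights(noise, shell_limit)
        lnl = -(shell_sums @ w)
        hi = self.n_shell if shell_limit is None else min(shell_limit + 1, self.n_shell)
        lnl -= (
            self.m_s[1:hi] * np.log(2.0 * np.pi * noise.sigma2[1:hi])
        ).sum()
        return lnl

    # -- reconstruction ---------------------------------------------------

    def reconstruct_class(self, weights: np.ndarray, epsilon_scale: float = 1e-3) -> VolumeGrid:
        """Responsibility-weighted direct Fourier reconstruction."""
        m = self.grid_shape[0]
        size = m * m * m
        num_re = np.zeros(size)
        num_im = np.zeros(size)
        den = np.zeros(size)
        for lo in range(0, self.n_img, self.batch):
            hi = min(lo + self.batch, self.n_img)
            wb = weights[lo:hi]
            if not np.any(wb > 0):
                continue
            idx8 = self.idx8[lo:hi].reshape(-1, 8)
            w8 = self.w8[lo:hi].reshape(-1, 8)
            vals = (wb[:, None] * self.ctfs[lo:hi] * self.data[lo:hi]).reshape(-1, 1)
            dvals = (wb[:, None] * self.ctfs[lo:hi] ** 2).reshape(-1, 1)
            flat_idx = idx8.ravel()
            num_re += np.bincount(flat_idx, weights=(w8 * vals.real).ravel(), minlength=size)
            num_im += np.bincount(flat_idx, weights=(w8 * vals.imag).ravel(), minlength=size)
            den += np.bincount(flat_idx, weights=(w8 * dvals).ravel(), minlength=size)
        nz = den > 0
        if not nz.any():
            raise ValueError("class received no data")
        eps = epsilon_scale * float(den[nz].mean())
        ratio = ((num_re + 1j * num_im) / (den + eps)).reshape(self.grid_shape)
        vol = ifftn_c(ratio).real * self.box
        n = self.box
        lo_c = (m - n) // 2
        cropped = vol[lo_c : lo_c + n, lo_c : lo_c + n, lo_c : lo_c + n]
        return VolumeGrid(cropped / gridding_correction(n, self.pad), self.pixel_size)


def _masked(ref: VolumeGrid, mask: SoftMask | None) -> VolumeGrid:
    return ref if mask is None else apply_mask(ref, mask)


def _sigma2_from_sums(engine: _Engine, shell_sums: np.ndarray, resp: np.ndarray) -> np.ndarray:
    """Responsibility-weighted per-shell variance estimate."""
    pooled = np.einsum("ik,iks->s", resp, shell_sums)
    denom = 2.0 * engine.n_img * np.maximum(engine.m_s, 1.0)
    sigma2 = pooled / denom
    floor = max(1e-30, 1e-8 * sigma2[1:].max()) if sigma2.size > 1 else 1e-30
    return np.maximum(sigma2, floor)


def init_classes(
    particles: ParticleSet,
    images: ImageStack,
    k: int,
    seed: int,
    mask: SoftMask | None = None,
    resolution_shell: int | None = None,
    initial_lowpass: float | None = None,
    _engine: _Engine | None = None,
) -> ClassModel:
    """Seeded random hard partition, one low-passed reconstruction per group.

    All groups see the same data distribution, so the K initial references
    differ only by sampling noise — the reproducible equivalent of starting
    identically and letting the random assignment break the symmetry.  An
    optional ``initial_lowpass`` (Angstrom) filters the initial references;
    robustness to reference sampling noise is normally handled by the
    coarse-to-fine schedule in :func:`classify` instead.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > len(particles):
        raise ValueError(f"K={k} exceeds particle count {len(particles)}")
    eng = _engine or _Engine(particles, images, resolution_shell)
    rng = np.random.default_rng(seed)
    labels = rng.permutation(len(particles)) % k
    lp = (
        None
        if initial_lowpass is None
        else make_lowpass(initial_lowpass, eng.box, eng.pixel_size)
    )
    refs = []
    fractions = np.empty(k)
    for j in range(k):
        w = (labels == j).astype(float)
        fractions[j] = w.mean()
        ref = eng.reconstruct_class(w)
        if lp is not None:
            ref = apply_radial_filter(ref, lp)
        refs.append(_masked(ref, mask))
    # initial noise: residuals against the pooled (single-class) reference
    pooled = _masked(eng.reconstruct_class(np.ones(eng.n_img)), mask)
    tmp = ClassModel(
        (pooled,),
        np.array([1.0]),
        NoiseSpectrum(np.ones(eng.n_shell)),
        mask,
        0,
        eng.smax,
    )
    sums = eng.residual_shell_sums(tmp)
    sigma2 = _sigma2_from_sums(eng, sums[:, 0:1, :], np.ones((eng.n_img, 1)))
    return ClassModel(
        tuple(refs), fractions, NoiseSpectrum(sigma2), mask, 0, eng.smax
    )


def e_step(
    model: ClassModel,
    particles: ParticleSet,
    images: ImageStack,
    _engine: _Engine | None = None,
):
    """Posterior responsibilities and per-particle log-evidence.

    Returns ``(resp, log_evidence, shell_sums)``; ``shell_sums`` carries the
    per-shell residual powers the M-step reuses for the noise update.
    """
    eng = _engine or _Engine(particles, images, model.resolution_shell)
    shell_sums = eng.residual_shell_sums(model)
    lnl = eng.log_likelihood(shell_sums, model.noise)
    if not np.all(np.isfinite(lnl)):
        bad = int(np.argwhere(~np.isfinite(lnl))[0][0])
        raise FloatingPointError(f"non-finite likelihood for particle {bad}")
    with np.errstate(divide="ignore"):
        joint = lnl + np.log(model.fractions)[None, :]
    log_ev = logsumexp(joint, axis=1)
    resp = np.exp(joint - log_ev[:, None])
    return resp, log_ev, shell_sums


def m_step(
    model: ClassModel,
    particles: ParticleSet,
    images: ImageStack,
    resp: np.ndarray,
    _engine: _Engine | None = None,
) -> ClassModel:
    """Update references, fractions and the noise spectrum.

    A class whose total responsibility vanishes keeps its previous reference
    and gets fraction 0 (flagged by that zero fraction).
    """
    eng = _engine or _Engine(particles, images, model.resolution_shell)
    resp = np.asarray(resp, dtype=float)
    fractions = resp.mean(axis=0)
    refs = []
    for k in range(model.n_classes):
        if resp[:, k].sum() <= 1e-12:
            refs.append(model.references[k])
            continue
        refs.append(_masked(eng.reconstruct_class(resp[:, k]), model.focus_mask))
    total = fractions.sum()
    updated = replace(
        model,
        references=tuple(refs),
        fractions=fractions / total if total > 0 else fractions,
        iteration=model.iteration + 1,
    )
    # conditional M-step for sigma^2: residuals against the *updated*
    # references, so each update maximizes its own coordinate of the
    # penalized objective (keeps EM ascent as exact as the reconstruction
    # approximation allows)
    new_sums = eng.residual_shell_sums(updated)
    sigma2 = _sigma2_from_sums(eng, new_sums, resp)
    return replace(updated, noise=NoiseSpectrum(sigma2))


def classify(
    particles: ParticleSet,
    images: ImageStack,
    k: int,
    mask: SoftMask | None = None,
    n_iter: int = 25,
    seed: int = 0,
    resolution_limit: float | None = None,
    coarse_limit: float | None = 12.0,
    coarse_iters: int = 6,
    initial_lowpass: float | None = None,
    batch: int = 256,
):
    """Fixed-orientation masked classification into K classes.

    Alternates E and M steps for exactly ``n_iter`` iterations (no
    convergence early-exit, for reproducibility).  ``resolution_limit`` is
    in Angstrom; the default stops two shells below Nyquist.

    Classification runs coarse-to-fine: the first ``coarse_iters``
    iterations score the likelihood only up to ``coarse_limit`` Angstrom.
    Class differences of interest live at low frequency, while the
    high-frequency content of freshly initialized references is sampling
    noise; restricting the early comparisons keeps responsibilities soft
    and lets the true class split grow before the full band opens up.
    Without this, low-noise data can freeze EM near its random initial
    partition, and heavily filtered initializations can stall symmetric.

    Returns ``(model, responsibilities, history)``; history records, per
    iteration, the class fractions, the mean per-particle log-evidence and
    the shell limit it was evaluated with (evidence values are comparable
    only between iterations with the same limit).
    """
    box = images.box
    if resolution_limit is None:
        res_shell = None
    else:
        res_shell = int(round(box * images.pixel_size / resolution_limit))
    eng = _Engine(particles, images, res_shell, batch=batch)
    model = init_classes(
        particles, images, k, seed, mask, initial_lowpass=initial_lowpass, _engine=eng
    )
    if coarse_limit is None:
        s_coarse = eng.smax
    else:
        s_coarse = int(round(box * images.pixel_size / coarse_limit))
        s_coarse = max(1, min(s_coarse, eng.smax))

    def shell_limit_for(iteration: int) -> int:
        return s_coarse if iteration < coarse_iters else eng.smax

    def posterior(lnl: np.ndarray, fractions: np.ndarray):
        with np.errstate(divide="ignore"):
            joint = lnl + np.log(fractions)[None, :]
        log_ev = logsumexp(joint, axis=1)
        return np.exp(joint - log_ev[:, None]), log_ev

    s_eff = shell_limit_for(0)
    sums = eng.residual_shell_sums(model)
    resp, log_ev = posterior(
        eng.log_likelihood(sums, model.noise, s_eff), model.fractions
    )

    def record():
        history.append(
            {
                "iteration": model.iteration,
                "fractions": model.fractions.copy(),
                "mean_log_evidence": float(log_ev.mean()),
                "shell_limit": s_eff,
            }
        )

    history: list[dict] = []
    record()
    for it in range(n_iter):
        s_next = shell_limit_for(it)
        if s_next != s_eff:
            # band change: re-baseline the current model's evidence in the
            # new band so the ascent guard compares like with like
            s_eff = s_next
            resp, log_ev = posterior(
                eng.log_likelihood(sums, model.noise, s_eff), model.fractions
            )
        mean_prev = float(log_ev.mean())
        fractions = resp.mean(axis=0)
        fractions = fractions / fractions.sum()
        refs_full = []
        for j in range(k):
            if resp[:, j].sum() <= 1e-12:
                refs_full.append(model.references[j])
            else:
                refs_full.append(_masked(eng.reconstruct_class(resp[:, j]), mask))
        # generalized-EM ascent guard: the fraction and noise updates are
        # exact conditional maximizers, so halving the reference step always
        # restores monotonicity when the approximate reconstruction overshoots
        step = 1.0
        for _attempt in range(7):
            refs_try = tuple(
                VolumeGrid(
                    (1.0 - step) * old.data + step * new.data, old.pixel_size
                )
                for old, new in zip(model.references, refs_full)
            )
            cand = replace(
                model, references=refs_try, fractions=fractions, iteration=it + 1
            )
            sums_try = eng.residual_shell_sums(cand)
            cand = replace(
                cand, noise=NoiseSpectrum(_sigma2_from_sums(eng, sums_try, resp))
            )
            resp_try, logev_try = posterior(
                eng.log_likelihood(sums_try, cand.noise, s_eff), cand.fractions
            )
            if float(logev_try.mean()) >= mean_prev - 1e-9 * abs(mean_prev):
                break
            step *= 0.5
        model, resp, log_ev, sums = cand, resp_try, logev_try, sums_try
        record()
    return model, resp, history


def select_classes(model: ClassModel, resp: np.ndarray, min_fraction: float = 0.0):
    """Hard-assigned particle indices per retained class.

    Argmax assignment with ties broken toward the lowest class index;
    classes with fraction below ``min_fraction`` are dropped.  Returns a
    list of ``{"class_index", "fraction", "indices"}`` dicts.
    """
    resp = np.asarray(resp, dtype=float)
    assigned = resp.argmax(axis=1)
    out = []
    for k in range(model.n_classes):
        frac = float(model.fractions[k])
        if frac < min_fraction:
            continue
        out.append(
            {
                "class_index": k,
                "fraction": frac,
                "indices": np.flatnonzero(assigned == k),
            }
        )
    return out
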