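"""Residual signal subtraction.

The central operation of the focused-classification workflow: for every
particle, subtract the CTF-affected projection of the part of the consensus
map one wants to ignore (V1) from the experimental image, leaving — up to
experimental noise — only the signal of the region of interest (V2).  The
particle's refined orientation and offsets from the consensus refinement
are used, so the projection is shifted into the particle frame before
subtraction; no rescaling of any kind is applied.
"""

from __future__ import annotations

import numpy as np

from .geometry import euler_to_matrix
from .io_formats import ImageStack, ParticleSet, VolumeGrid
from .projection import FourierVolume, project

__all__ = ["subtract_signal"]


def subtract_signal(
    particles: ParticleSet,
    images: ImageStack,
    v1: VolumeGrid,
    apply_ctf: bool = True,
    stack_name: str = "subtracted.mrcs",
) -> tuple[ImageStack, ParticleSet]:
    """Subtract ``CTF_i * P(V1)`` at each particle's pose from each image.

    Returns a new stack and a metadata copy whose ``image_ref`` points into
    it; order and every other field are preserved verbatim.  With
    ``apply_ctf=False`` the plain projection is subtracted (only sensible
    for data that were not CTF-modulated).
    """
    if len(particles) != len(images):
        raise ValueError("particle count does not match image count")
    if v1.box != images.box or not np.isclose(v1.pixel_size, images.pixel_size):
        raise ValueError(
            f"grid mismatch: map {v1.box}px/{v1.pixel_size}A vs "
            f"images {images.box}px/{images.pixel_size}A"
        )
    fv = FourierVolume(v1)
    out = np.empty_like(images.data)
    new_records = []
    for i, rec in enumerate(particles):
        proj = project(
            fv,
            euler_to_matrix(rec.rot, rec.tilt, rec.psi),
            origin_x=rec.origin_x,
            origin_y=rec.origin_y,
            ctf=rec.ctf if apply_ctf else None,
        )
        out[i] = images.data[i] - proj.data
        new_records.append(
            rec.__class__(
                image_ref=(stack_name, i + 1),
                rot=rec.rot,
                tilt=rec.tilt,
                psi=rec.psi,
                origin_x=rec.origin_x,
                origin_y=rec.origin_y,
                ctf=rec.ctf,
                class_label=rec.class_label,
                random_subset=rec.random_subset,
            )
        )
    new_set = ParticleSet(
        tuple(new_records), pixel_size=particles.pixel_size, box=particles.box
    )
    return ImageStack(out, images.pixel_size), new_set
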