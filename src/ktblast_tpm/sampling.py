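"""Cartesian Fourier encoding, k-t lattice undersampling and training extraction.

Conventions
-----------
Image arrays are (..., n_readout, n_pe): readout along rows, phase encode
along columns.  k-space is stored centred: after `image_to_kspace` the DC
sample sits at index ``n // 2`` along each axis (0-based).  All transforms
are unitary ("ortho" normalization), so round trips are exact and noise
variance is preserved between domains.

The k-t sampling schedule is a sheared lattice: cardiac phase ``t`` samples
every R-th phase-encode line starting at offset ``t mod R``, so any R
consecutive phases jointly sample every line exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.fft import fftn, fftshift, ifftn, ifftshift

from .phantom import EncodedCine

__all__ = [
    "KSpaceSeries",
    "KTSamplingPattern",
    "TrainingSet",
    "image_to_kspace",
    "kspace_to_image",
    "to_kspace",
    "make_kt_pattern",
    "undersample",
    "acquire_training",
    "crop_pe",
    "pad_pe_images",
]


def image_to_kspace(img: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centred unitary 2-D DFT (image -> k-space, DC at n//2)."""
    return fftshift(fftn(ifftshift(img, axes=axes), axes=axes, norm="ortho"), axes=axes)


def kspace_to_image(k: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centred unitary inverse 2-D DFT (k-space -> image)."""
    return fftshift(ifftn(ifftshift(k, axes=axes), axes=axes, norm="ortho"), axes=axes)


@dataclass
class KSpaceSeries:
    """Complex k-space stacks, shape (n_enc, n_phases, n_ro, n_pe).

    ``sampled`` is a boolean (n_phases, n_pe) mask over phase-encode lines,
    shared by all encodings (the encodings repeat the schedule in
    consecutive heartbeats).
    """

    data: np.ndarray
    sampled: np.ndarray
    noise_sd: float = 0.0

    @property
    def n_enc(self) -> int:
        return self.data.shape[0]

    @property
    def n_phases(self) -> int:
        return self.data.shape[1]

    @property
    def n_ro(self) -> int:
        return self.data.shape[2]

    @property
    def n_pe(self) -> int:
        return self.data.shape[3]


@dataclass
class KTSamplingPattern:
    """Sheared k-t lattice: phase t samples lines j with (j - t) % R == 0."""

    R: int
    n_pe: int
    n_phases: int

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.n_phases % self.R != 0:
            raise ValueError(
                f"n_phases={self.n_phases} must be a multiple of R={self.R}"
            )

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(self.n_phases) % self.R

    def mask(self) -> np.ndarray:
        """Boolean (n_phases, n_pe) sampling mask."""
        t = np.arange(self.n_phases)[:, None]
        j = np.arange(self.n_pe)[None, :]
        return (j - t) % self.R == 0

    @classmethod
    def from_mask(cls, sampled: np.ndarray) -> "KTSamplingPattern":
        """Recover the lattice from a sampling mask; error if not a lattice."""
        n_phases, n_pe = sampled.shape
        nnz = int(sampled.sum())
        if nnz == 0:
            raise ValueError("empty sampling mask")
        R = round(n_phases * n_pe / nnz)
        pat = cls(R=R, n_pe=n_pe, n_phases=n_phases)
        if not np.array_equal(pat.mask(), sampled):
            raise ValueError("sampling mask is not a sheared k-t lattice")
        return pat


@dataclass
class TrainingSet:
    """Central low-resolution, fully time-sampled k-space block.

    ``data`` has shape (n_enc, n_phases, n_ro, n_lines); ``line_indices``
    are the phase-encode column indices of the block in the parent grid of
    ``n_pe`` lines.
    """

    data: np.ndarray
    line_indices: np.ndarray
    n_pe: int
    noise_sd: float = 0.0

    @property
    def n_lines(self) -> int:
        return self.data.shape[3]


def to_kspace(
    enc: EncodedCine | np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> KSpaceSeries:
    """Fourier-encode complex images and add complex Gaussian k-space noise.

    ``noise_sd`` is the standard deviation of each complex sample
    (real and imaginary parts each have sd ``noise_sd / sqrt(2)``).
    """
    images = enc.images if isinstance(enc, EncodedCine) else np.asarray(enc)
    k = image_to_kspace(images)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        noise = gen.standard_normal(k.shape) + 1j * gen.standard_normal(k.shape)
        k = k + noise * (noise_sd / np.sqrt(2.0))
    sampled = np.ones((k.shape[1], k.shape[3]), dtype=bool)
    return KSpaceSeries(data=k, sampled=sampled, noise_sd=float(noise_sd))


def make_kt_pattern(n_pe: int, n_phases: int, R: int) -> KTSamplingPattern:
    """Sheared-lattice schedule with offsets ``t mod R``."""
    return KTSamplingPattern(R=R, n_pe=n_pe, n_phases=n_phases)


def undersample(k: KSpaceSeries, pat: KTSamplingPattern) -> KSpaceSeries:
    """Zero and mark the phase-encode lines not on the lattice."""
    if (k.n_pe, k.n_phases) != (pat.n_pe, pat.n_phases):
        raise ValueError("k-space shape does not match sampling pattern")
    m = pat.mask()
    data = k.data * m[None, :, None, :]
    return KSpaceSeries(data=data, sampled=m & k.sampled, noise_sd=k.noise_sd)


def acquire_training(k: KSpaceSeries, training_lines: int) -> TrainingSet:
    """Extract the central ``training_lines`` phase-encode lines, all phases.

    The block is centred on the DC line (index n_pe // 2); noise included.
    """
    if training_lines < 1:
        raise ValueError("training_lines must be >= 1")
    if training_lines > k.n_pe:
        raise ValueError("training_lines exceeds the phase-encode matrix")
    start = k.n_pe // 2 - training_lines // 2
    idx = np.arange(start, start + training_lines)
    return TrainingSet(
        data=k.data[:, :, :, idx].copy(),
        line_indices=idx,
        n_pe=k.n_pe,
        noise_sd=k.noise_sd,
    )


def crop_pe(k: KSpaceSeries, n_pe_new: int) -> KSpaceSeries:
    """Keep the central ``n_pe_new`` phase-encode lines (DC-centred block).

    Amplitudes are rescaled by sqrt(n_pe_new / n_pe) so that smooth image
    values are preserved under the unitary transforms.
    """
    if not 0 < n_pe_new <= k.n_pe:
        raise ValueError("invalid crop size")
    if n_pe_new == k.n_pe:
        return k
    start = k.n_pe // 2 - n_pe_new // 2
    scale = np.sqrt(n_pe_new / k.n_pe)
    data = k.data[:, :, :, start : start + n_pe_new] * scale
    sampled = k.sampled[:, start : start + n_pe_new]
    return KSpaceSeries(data=data, sampled=sampled, noise_sd=k.noise_sd * scale)


def pad_pe_images(images: np.ndarray, n_pe_full: int) -> np.ndarray:
    """Zero-pad image series along phase encode back to ``n_pe_full`` columns.

    Transforms to k-space, pads symmetrically about DC, and transforms back
    with amplitude-preserving rescaling (sinc interpolation in space).
    """
    n_pe = images.shape[-1]
    if n_pe_full < n_pe:
        raise ValueError("target size smaller than input")
    if n_pe_full == n_pe:
        return images
    k = image_to_kspace(images)
    pad_left = n_pe_full // 2 - n_pe // 2
    pad = [(0, 0)] * (k.ndim - 1) + [(pad_left, n_pe_full - n_pe - pad_left)]
    k_pad = np.pad(k, pad)
    return kspace_to_image(k_pad) * np.sqrt(n_pe_full / n_pe)
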