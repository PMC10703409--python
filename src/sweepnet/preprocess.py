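"""Haplotype-matrix preprocessing into fixed-size model-ready images.

The pipeline follows the common CNN-for-sweeps conventions: recode alleles
to major/minor polarization, drop sites with minor-allele frequency below
1%, group identical haplotypes into blocks sorted by descending frequency
(most common haplotype on top), and force a common image width by one of
three strategies:

``resize``
    skimage's resizing algorithm (Gaussian anti-alias filter when
    downsampling, order-1 spline interpolation, reflect boundary) to a
    fixed width (128 by default).
``zero_pad``
    pad with columns of zeros, split across both edges, to the dataset's
    maximum width rounded up to the nearest multiple of 10.
``trim``
    keep the centered window of the dataset's minimum width rounded down
    to the nearest multiple of 10.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage.transform import resize as _skimage_resize

from .demography import HaplotypeMatrix, ParameterError

__all__ = [
    "PreprocessConfig",
    "ImageTensor",
    "FormatError",
    "polarize_major_minor",
    "filter_minor_allele",
    "sort_rows_frequency_blocks",
    "standardize_width",
    "resize_width",
    "preprocess_matrix",
    "preprocess_dataset",
    "read_vcf_haplotypes",
]


class FormatError(ValueError):
    """Input does not satisfy the expected format."""


WidthStrategy = Literal["resize", "zero_pad", "trim"]


@dataclass(frozen=True)
class PreprocessConfig:
    polarization: Literal["major_minor", "ancestral_derived"] = "major_minor"
    min_maf: float = 0.01
    row_sorting: Literal["frequency_blocks", "none"] = "frequency_blocks"
    width_strategy: WidthStrategy = "resize"
    target_width: int | None = None  # None = auto (128 for resize, data-driven otherwise)
    target_height: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf < 0.5:
            raise ParameterError("min_maf must lie in [0, 0.5)")
        if self.target_width is not None and self.target_width <= 0:
            raise ParameterError("target_width must be positive")


@dataclass
class ImageTensor:
    """Fixed-width real-valued image with preprocessing provenance."""

    pixels: np.ndarray  # (height, width) float32 in [0, 1]
    source_width: int
    config_provenance: PreprocessConfig | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise FormatError("image must be 2-D")


# ---------------------------------------------------------------------------
# Column-wise operations
# ---------------------------------------------------------------------------


def _check_binary(m: HaplotypeMatrix) -> None:
    if not set(np.unique(m.alleles)) <= {0, 1}:
        raise FormatError("matrix must be binary")


def polarize_major_minor(m: HaplotypeMatrix) -> HaplotypeMatrix:
    """Recode columns so allele 1 is the minor allele.

    Columns where the derived allele is the major allele are flipped;
    exact 50/50 ties keep their original coding.
    """
    _check_binary(m)
    freq = m.alleles.mean(axis=0)
    flip = freq > 0.5
    alleles = np.where(flip[None, :], 1 - m.alleles, m.alleles)
    prov = dict(m.provenance)
    prov["polarization"] = "major_minor"
    return HaplotypeMatrix(alleles=alleles, positions=m.positions, label=m.label, provenance=prov)


def filter_minor_allele(m: HaplotypeMatrix, min_maf: float = 0.01) -> HaplotypeMatrix:
    """Drop columns with minor-allele frequency strictly below ``min_maf``."""
    freq = m.alleles.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= min_maf
    prov = dict(m.provenance)
    prov["min_maf"] = min_maf
    if keep.sum() == 0:
        prov["empty_after_filter"] = True
    return HaplotypeMatrix(
        alleles=m.alleles[:, keep], positions=m.positions[keep], label=m.label, provenance=prov
    )


def sort_rows_frequency_blocks(m: HaplotypeMatrix) -> HaplotypeMatrix:
    """Group identical haplotypes and order blocks by descending frequency.

    The most frequent haplotype occupies the top rows.  Equal-frequency
    blocks are ordered lexicographically by their bit string, which makes
    the sort deterministic and invariant to any input row permutation.
    """
    _check_binary(m)
    if m.n_haplotypes == 0:
        return m
    uniq, counts = np.unique(m.alleles, axis=0, return_counts=True)
    # np.unique returns rows lexicographically sorted; stable sort on -count
    # keeps that order within equal counts.
    order = np.argsort(-counts, kind="stable")
    rows = np.repeat(uniq[order], counts[order], axis=0)
    return HaplotypeMatrix(
        alleles=rows, positions=m.positions, label=m.label, provenance=dict(m.provenance)
    )


# ---------------------------------------------------------------------------
# Width standardization
# ---------------------------------------------------------------------------


def resize_width(img: np.ndarray, target_width: int) -> np.ndarray:
    """Resize along the column axis with skimage's anti-aliased order-1
    interpolation (anti-alias Gaussian applied only when downsampling)."""
    if target_width <= 0:
        raise ParameterError("target_width must be positive")
    img = np.asarray(img, dtype=float)
    if img.shape[1] == target_width:
        return img.astype(np.float32)
    out = _skimage_resize(
        img,
        (img.shape[0], target_width),
        order=1,
        mode="reflect",
        anti_aliasing=img.shape[1] > target_width,
        preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _pad_width(img: np.ndarray, target_width: int) -> np.ndarray:
    deficit = target_width - img.shape[1]
    left = deficit // 2
    right = deficit - left  # odd remainder goes to the right edge
    return np.pad(img, ((0, 0), (left, right)))


def _trim_width(img: np.ndarray, target_width: int) -> np.ndarray:
    excess = img.shape[1] - target_width
    start = excess // 2  # centered window (sweep site sits mid-region)
    return img[:, start : start + target_width]


def _round_up(x: int, mult: int = 10) -> int:
    return int(np.ceil(x / mult) * mult)


def _round_down(x: int, mult: int = 10) -> int:
    return int(np.floor(x / mult) * mult)


def resolve_target_width(
    widths: Sequence[int], config: PreprocessConfig
) -> int:
    if config.target_width is not None:
        return config.target_width
    if config.width_strategy == "resize":
        return 128
    if config.width_strategy == "zero_pad":
        return _round_up(max(widths))
    target = _round_down(min(widths))
    if target <= 0:
        raise ParameterError(
            f"trim target width {target} is not positive (narrowest image: {min(widths)})"
        )
    return target


def standardize_width(
    matrices: Sequence[HaplotypeMatrix],
    config: PreprocessConfig,
    target_width: int | None = None,
) -> list[ImageTensor]:
    """Convert matrices to a common width per ``config.width_strategy``.

    All outputs share one width; ``zero_pad``/``trim`` keep pixels binary,
    ``resize`` keeps them in [0, 1].
    """
    if len(matrices) == 0:
        raise ParameterError("empty image list")
    heights = {m.n_haplotypes for m in matrices}
    if len(heights) != 1:
        raise ParameterError("images must share a common height")
    widths = [m.n_sites for m in matrices]
    if target_width is None:
        target_width = resolve_target_width(widths, config)
    out = []
    for m in matrices:
        img = m.alleles.astype(np.float32)
        if config.width_strategy == "resize":
            pix = resize_width(img, target_width)
        elif config.width_strategy == "zero_pad":
            if img.shape[1] > target_width:
                raise ParameterError("image wider than zero_pad target")
            pix = _pad_width(img, target_width)
        elif config.width_strategy == "trim":
            if img.shape[1] < target_width:
                raise ParameterError("image narrower than trim target")
            pix = _trim_width(img, target_width)
        else:  # pragma: no cover - guarded by Literal type
            raise ParameterError(f"unknown width strategy {config.width_strategy!r}")
        out.append(
            ImageTensor(
                pixels=pix,
                source_width=m.n_sites,
                config_provenance=config,
                label=m.label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def preprocess_matrix(m: HaplotypeMatrix, config: PreprocessConfig) -> HaplotypeMatrix:
    """Polarize, filter and sort one matrix (all steps before width
    standardization, in that order)."""
    if config.polarization == "major_minor":
        m = polarize_major_minor(m)
    if config.min_maf > 0:
        m = filter_minor_allele(m, config.min_maf)
    if config.row_sorting == "frequency_blocks":
        m = sort_rows_frequency_blocks(m)
    return m

def preprocess_dataset(
    matrices: Sequence[HaplotypeMatrix], config: PreprocessConfig
) -> list[ImageTensor]:
    prepared = [preprocess_matrix(m, config) for m in matrices]
    return standardize_width(prepared, config)


def stack_images(images: Iterable[ImageTensor]) -> np.ndarray:
    """Stack image tensors into an (n, height, width) float32 array."""
    return np.stack([im.pixels for im in images]).astype(np.float32)


# ---------------------------------------------------------------------------
# VCF ingestion (optional real-data input)
# ---------------------------------------------------------------------------


def read_vcf_haplotypes(
    path: str | Path,
    region: tuple[str, int, int] | None = None,
) -> HaplotypeMatrix:
    """Read phased genotypes from a VCF into a haplotype matrix.

    Diploid samples contribute two rows each; multi-allelic sites and sites
    with missing or unphased genotypes are dropped.  ``region`` is an
    optional ``(chrom, start_bp, end_bp)`` filter applied while scanning.
    """
    from cyvcf2 import VCF  # local import: cyvcf2 touches file descriptors

    rows: list[np.ndarray] = []
    positions: list[float] = []
    vcf = VCF(str(path))
    try:
        for var in vcf:
            if region is not None:
                chrom, start, end = region
                if var.CHROM != chrom or not (start <= var.POS < end):
                    continue
            if len(var.ALT) != 1:
                continue
            gt = np.asarray([g[:2] for g in var.genotypes])
            if (gt < 0).any():
                continue
            if positions and var.POS <= positions[-1]:
                continue  # duplicate/overlapping records
            positions.append(float(var.POS))
            rows.append(gt.reshape(-1).astype(np.uint8))
    finally:
        vcf.close()
    if not rows:
        raise FormatError("no usable biallelic phased sites in VCF")
    alleles = np.stack(rows, axis=1)
    return HaplotypeMatrix(
        alleles=alleles,
        positions=np.asarray(positions),
        provenance={"source": str(path), "region": region},
    )
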