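"""Synthetic MALDI-style datacube generator.

Emulates the statistical structure of a multi-region MALDI mass spectrometry
imaging experiment, without depending on external atlases or metabolite
databases:

* a procedural tissue mask: an elliptical foreground on a rectangular grid,
  partitioned into ``n_regions`` contiguous regions by a seeded Voronoi
  tessellation;
* per-species peak series: a random monoisotopic mass in 100–1000 Th, three
  adduct offsets ([M+H]+, [M+Na]+, [M+K]+) and a short isotope envelope with
  geometric intensity decay;
* per-region characteristic intensity ratios for every species, with
  multiplicative, normally distributed fluctuation (coefficient of variation
  ``noise_cv``), truncated at zero;
* shared matrix-background peaks (a blank-matrix spectrum common to every
  region).

On top of the base generator, three dataset transforms reproduce standard
stress tests for dimensionality-reduction evaluation: region homogenization
(pull every pixel toward the global mean), a disparate-cluster bootstrap
(duplicate one region's spectra until it dominates), and vertical
concatenation of two cubes.

All randomness flows through ``numpy.random.default_rng(seed)``; every
generator is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .datacube import MSIDataCube, region_mean_spectra
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "SyntheticSpec",
    "generate_region_mask",
    "synthesize_cube",
    "make_cube",
    "homogenize",
    "make_disparate",
    "concatenate_cubes",
]

#: average isotope spacing (Th) used for envelope peak positions
_ISOTOPE_SPACING = 1.00335

#: default adduct offsets (Th): [M+H]+, [M+Na]+, [M+K]+
DEFAULT_ADDUCTS = (1.00728, 22.98922, 38.96316)

#: relative ion yields of the three adducts
_ADDUCT_WEIGHTS = (1.0, 0.6, 0.3)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``region_intensity_ratios`` (k × n_species, n_species = n_regions ×
    species_per_region) may be supplied explicitly; by default each species
    is "characteristic" of one region (elevated ratio there, low baseline
    elsewhere), which yields regions with distinct template spectra — the
    structure the evaluation metrics exercise.
    """

    grid: tuple[int, int] = (64, 42)
    n_regions: int = 8
    species_per_region: int = 2
    n_matrix_peaks: int = 6
    adduct_offsets: Sequence[float] = DEFAULT_ADDUCTS
    isotope_peaks: int = 3
    isotope_decay: float = 0.5
    region_intensity_ratios: np.ndarray | None = None
    noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValidationError("n_regions must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        self.adduct_offsets = tuple(float(a) for a in self.adduct_offsets)
        if len(set(self.adduct_offsets)) != len(self.adduct_offsets):
            raise ValidationError("adduct offsets must be distinct")
        if self.region_intensity_ratios is not None:
            r = np.asarray(self.region_intensity_ratios, dtype=np.float64)
            if r.ndim != 2 or r.shape[0] != self.n_regions:
                raise ValidationError("region_intensity_ratios must be (n_regions, n_species)")
            if np.any(r < 0):
                raise ValidationError("intensity ratios must be non-negative")
            self.region_intensity_ratios = r

    @property
    def n_species(self) -> int:
        if self.region_intensity_ratios is not None:
            return self.region_intensity_ratios.shape[1]
        return self.n_regions * self.species_per_region

    @property
    def n_channels(self) -> int:
        return self.n_species * len(self.adduct_offsets) * self.isotope_peaks + self.n_matrix_peaks

    # YAML round trip --------------------------------------------------
    def to_yaml(self) -> str:
        d = self.__dict__.copy()
        d["grid"] = list(self.grid)
        d["adduct_offsets"] = [float(a) for a in self.adduct_offsets]
        if d["region_intensity_ratios"] is not None:
            d["region_intensity_ratios"] = np.asarray(d["region_intensity_ratios"]).tolist()
        return yaml.safe_dump(d)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        d = yaml.safe_load(text)
        d["grid"] = tuple(d["grid"])
        if d.get("region_intensity_ratios") is not None:
            d["region_intensity_ratios"] = np.asarray(d["region_intensity_ratios"], dtype=np.float64)
        return cls(**d)


# ---------------------------------------------------------------------------
# Region mask
# ---------------------------------------------------------------------------

def generate_region_mask(
    grid: tuple[int, int], n_regions: int, seed: int = 0
) -> np.ndarray:
    """Procedural tissue mask: elliptical foreground, Voronoi regions.

    Returns an ``(height, width)`` integer array; 0 is background, labels
    1..k partition the foreground into contiguous regions. Each Voronoi site
    is a foreground cell drawn without replacement, so every region contains
    at least its own site. Deterministic given ``seed``.
    """
    width, height = int(grid[0]), int(grid[1])
    if n_regions < 1:
        raise ValidationError("n_regions must be >= 1")
    yy, xx = np.mgrid[0:height, 0:width]
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    # ellipse with semi-axes at 95% of the half-extent
    fg = ((xx - cx) / (0.95 * width / 2)) ** 2 + ((yy - cy) / (0.95 * height / 2)) ** 2 <= 1.0
    fg_idx = np.flatnonzero(fg.ravel())
    if n_regions > fg_idx.size:
        raise ValidationError(
            f"n_regions={n_regions} exceeds the {fg_idx.size} foreground cells"
        )
    rng = np.random.default_rng(seed)
    sites = rng.choice(fg_idx, size=n_regions, replace=False)
    sx, sy = sites % width, sites // width
    fx, fy = fg_idx % width, fg_idx // width
    d2 = (fx[:, None] - sx[None, :]) ** 2 + (fy[:, None] - sy[None, :]) ** 2
    assign = np.argmin(d2, axis=1) + 1  # argmin ties -> lowest site index
    mask = np.zeros((height, width), dtype=np.int64)
    mask.ravel()[fg_idx] = assign
    return mask


# ---------------------------------------------------------------------------
# Spectrum templates and cube synthesis
# ---------------------------------------------------------------------------

def _build_templates(spec: SyntheticSpec, rng: np.random.Generator):
    """Random m/z axis plus the (k, n_channels) noise-free template matrix."""
    n_sp = spec.n_species
    n_ad = len(spec.adduct_offsets)
    n_iso = spec.isotope_peaks
    mono = np.sort(rng.uniform(100.0, 1000.0, size=n_sp))
    # peak positions: species × adduct × isotope
    pos = (
        mono[:, None, None]
        + np.asarray(spec.adduct_offsets)[None, :, None]
        + _ISOTOPE_SPACING * np.arange(n_iso)[None, None, :]
    ).ravel()
    matrix_pos = rng.uniform(100.0, 400.0, size=spec.n_matrix_peaks)  # CHCA-like low-mass clusters
    mz = np.concatenate([pos, matrix_pos])
    order = np.argsort(mz)
    # collision of two channels at the same m/z is vanishingly unlikely but
    # would break strict monotonicity; nudge deterministically if it happens
    mz_sorted = mz[order]
    dup = np.flatnonzero(np.diff(mz_sorted) <= 0)
    for j in dup:
        mz_sorted[j + 1] = np.nextafter(mz_sorted[j], np.inf)

    if spec.region_intensity_ratios is not None:
        ratios = spec.region_intensity_ratios
    else:
        # low baseline everywhere, each species elevated in its home region
        ratios = rng.uniform(0.02, 0.2, size=(spec.n_regions, n_sp))
        home = np.arange(n_sp) % spec.n_regions
        ratios[home, np.arange(n_sp)] = rng.uniform(1.0, 8.0, size=n_sp)

    # expand species ratios over adducts and isotopes
    weights = (
        np.asarray(_ADDUCT_WEIGHTS[:n_ad])[None, :, None]
        * (spec.isotope_decay ** np.arange(n_iso))[None, None, :]
    )
    species_part = (ratios[:, :, None, None] * weights[None, :, :, :]).reshape(
        spec.n_regions, n_sp * n_ad * n_iso
    )
    matrix_row = rng.uniform(0.5, 2.0, size=spec.n_matrix_peaks)
    templates = np.concatenate(
        [species_part, np.broadcast_to(matrix_row, (spec.n_regions, spec.n_matrix_peaks))],
        axis=1,
    )[:, order]
    return mz_sorted, templates


def synthesize_cube(spec: SyntheticSpec, mask: np.ndarray) -> MSIDataCube:
    """Populate a region mask with noisy spectra.

    Pixel intensity for channel ``j`` in region ``r`` is drawn as
    ``template[r, j] * (1 + eps)`` with ``eps ~ Normal(0, noise_cv)``,
    truncated at zero. Matrix-background channels share one template row
    across all regions. Pixels are emitted in canonical row-major (y, x)
    order; ``region_labels`` come from the mask.
    """
    mask = np.asarray(mask)
    fg = mask > 0
    if not fg.any():
        raise DegenerateInputError("mask has no foreground cells")
    labels_present = np.unique(mask[fg])
    if labels_present.max() > spec.n_regions:
        raise ValidationError("mask labels exceed spec.n_regions")
    rng = np.random.default_rng(spec.seed)
    mz, templates = _build_templates(spec, rng)
    height, width = mask.shape
    ys, xs = np.nonzero(fg)  # row-major (y, x) order
    labels = mask[ys, xs]
    base = templates[labels - 1]
    noise = rng.normal(0.0, spec.noise_cv, size=base.shape) if spec.noise_cv > 0 else 0.0
    intensities = np.maximum(base * (1.0 + noise), 0.0)
    return MSIDataCube(
        intensities=intensities,
        mz_axis=mz,
        coords=np.column_stack([xs, ys]),
        mask_shape=(width, height),
        region_labels=labels,
        metadata={"generator": "synthetic_msi", "spec": yaml.safe_load(spec.to_yaml())},
    )


def make_cube(spec: SyntheticSpec) -> MSIDataCube:
    """Convenience: mask + cube in one call (mask seeded from ``spec.seed``)."""
    mask = generate_region_mask(spec.grid, spec.n_regions, seed=spec.seed)
    return synthesize_cube(spec, mask)


# ---------------------------------------------------------------------------
# Dataset transforms
# ---------------------------------------------------------------------------

def homogenize(cube: MSIDataCube, s: float, clip_negative: bool = False) -> MSIDataCube:
    """Blend every pixel toward the global mean spectrum.

    Each pixel ``p_i`` in region ``r`` becomes ``p_i - s*mu_r + s*mu_w``:
    the pixel keeps its own deviation from its region mean while the region
    mean itself is moved a fraction ``s`` of the way to the whole-dataset
    mean. After the transform each region's mean equals
    ``(1 - s) * mu_r + s * mu_w`` exactly. ``s = 0`` is the identity;
    ``s = 0.9`` gives pixels that carry 90% global / 10% region character.

    The formula can produce negative intensities; they are kept by default
    and clipped at zero only when ``clip_negative`` is set.
    """
    if not 0.0 <= s <= 1.0:
        raise ValidationError("s must lie in [0, 1]")
    means, mu_w = region_mean_spectra(cube)  # raises if labels missing
    out = cube.intensities.copy()
    labels = cube.region_labels
    for r, mu_r in means.items():
        sel = labels == r
        out[sel] = out[sel] - s * mu_r + s * mu_w
    if clip_negative:
        out = np.maximum(out, 0.0)
    new = cube.copy()
    new.intensities = out
    new.metadata = {**cube.metadata, "homogenized_s": s}
    return new


def make_disparate(
    cube: MSIDataCube, region_id: int, n_bootstrap: int, seed: int = 0
) -> MSIDataCube:
    """Bootstrap-enlarge one region so its cluster dominates the dataset.

    ``n_bootstrap`` spectra are sampled with replacement from ``region_id``
    and appended after the original pixels (which are preserved bit-exactly
    as a prefix). Appended pixels are laid out row-major on new rows below
    the original mask, so the grid height grows by
    ``ceil(n_bootstrap / width)``.
    """
    if cube.region_labels is None:
        raise ValidationError("make_disparate requires region_labels")
    if n_bootstrap < 0:
        raise ValidationError("n_bootstrap must be >= 0")
    pool = np.flatnonzero(cube.region_labels == region_id)
    if pool.size == 0:
        raise DegenerateInputError(f"region {region_id} is empty")
    if n_bootstrap == 0:
        return cube.copy()
    rng = np.random.default_rng(seed)
    picks = rng.choice(pool, size=n_bootstrap, replace=True)
    width, height = cube.mask_shape
    extra_rows = -(-n_bootstrap // width)  # ceil
    offsets = np.arange(n_bootstrap)
    new_coords = np.column_stack([offsets % width, height + offsets // width])
    new = MSIDataCube(
        intensities=np.vstack([cube.intensities, cube.intensities[picks]]),
        mz_axis=cube.mz_axis.copy(),
        coords=np.vstack([cube.coords, new_coords]),
        mask_shape=(width, height + extra_rows),
        region_labels=np.concatenate([cube.region_labels, cube.region_labels[picks]]),
        metadata={
            **cube.metadata,
            "disparate_region": int(region_id),
            "n_bootstrap": int(n_bootstrap),
        },
    )
    return new


def concatenate_cubes(a: MSIDataCube, b: MSIDataCube) -> MSIDataCube:
    """Stack two cubes: ``a``'s mask above ``b``'s, pixels of ``a`` first.

    Both cubes must share an identical m/z axis. ``b``'s region labels are
    offset by ``a``'s maximum label so regions stay distinct; the pairing
    (original label in ``b`` → shifted label) is recorded in metadata as
    ``paired_regions``.
    """
    if not np.array_equal(a.mz_axis, b.mz_axis):
        raise ValidationError("cubes must share an identical m/z axis to concatenate")
    wa, ha = a.mask_shape
    wb, hb = b.mask_shape
    width = max(wa, wb)
    b_coords = b.coords.copy()
    b_coords[:, 1] += ha
    la = a.region_labels if a.region_labels is not None else np.zeros(a.n_pixels, dtype=np.int64)
    lb = b.region_labels if b.region_labels is not None else np.zeros(b.n_pixels, dtype=np.int64)
    offset = int(la.max()) if la.size else 0
    lb_shifted = np.where(lb > 0, lb + offset, 0)
    pairing = {int(r): int(r + offset) for r in np.unique(lb[lb > 0])}
    return MSIDataCube(
        intensities=np.vstack([a.intensities, b.intensities]),
        mz_axis=a.mz_axis.copy(),
        coords=np.vstack([a.coords, b_coords]),
        mask_shape=(width, ha + hb),
        region_labels=np.concatenate([la, lb_shifted]),
        metadata={"concatenated": True, "paired_regions": pairing},
    )
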