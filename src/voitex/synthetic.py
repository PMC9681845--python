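"""Seeded 3-D lesion phantoms and labeled two-class cohorts.

Patient scans behind the study design are not publicly deposited, so the
package carries a generator that emulates their statistical structure: an
18-subject cohort (8 "AB-like" heterogeneous lesions, 10 "OKC-like"
homogeneous ones) of T2-like volumes with anisotropic voxels
(0.79 x 1.15 x 4.00 mm) and ellipsoidal VOI masks.

Each lesion is a textured rim around a near-constant inner core (the
analogue of a fluid pocket, whose relative size varies per subject
independently of class):

* rim texture: white Gaussian noise smoothed at the class *granularity*
  (voxels), standardized, mapped through the monotone histogram transform
  ``u -> u**gamma`` on the Gaussian CDF scale, plus independent additive
  noise. Smaller granularity raises entropy and contrast after
  quantization; ``gamma`` shifts where the intensity bulk sits after
  per-VOI min-max binning and hence the sum average (gamma < 1 pushes mass
  toward high levels and raises it);
* core: an inner concentric ellipsoid at a fixed intensity quantile of the
  rim, with only slight noise. The jittered core fraction gives homogeneity
  and uniformity a variation axis of their own.

The heterogeneous (AB-like) class uses small granularity and gamma < 1
(higher entropy, higher sum average); the homogeneous (OKC-like) class the
opposite. Background voxels outside the mask are generated but never enter
the analysis.

Everything is reproducible: per-subject seeds derive deterministically from
the cohort's master seed and are recorded in the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import VolumeWithMask, write_volume_with_mask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "write_cohort",
    "heterogeneous_template",
    "homogeneous_template",
]

DEFAULT_SHAPE = (48, 48, 24)
DEFAULT_SPACING = (0.79, 1.15, 4.00)


@dataclass(frozen=True)
class PhantomSpec:
    """One synthetic lesion volume.

    Parameters
    ----------
    shape, spacing
        Grid dimensions (voxels) and voxel edge lengths (mm). Spacing is
        metadata only: texture offsets are counted in voxels.
    semi_axes
        Ellipsoid lesion semi-axes in voxels; must fit inside the grid.
    texture_class
        ``"heterogeneous"`` (AB-like) or ``"homogeneous"`` (OKC-like).
    granularity
        Gaussian smoothing length (voxels) of the rim texture; > 0.
    histogram_shape
        Power-transform exponent gamma applied to the Gaussian CDF of the
        smoothed field; gamma < 1 concentrates intensity mass near the top
        of the range (raising sum average), gamma > 1 near the bottom.
    noise_sd
        Additive noise inside the lesion, relative to the rim's intensity
        spread.
    core_fraction
        Volume fraction of the near-constant inner core, in [0, 0.9].
    core_quantile
        Rim-intensity quantile at which the core sits.
    core_noise_sd
        Intensity spread of the core relative to the lesion range; controls
        how many gray levels the core occupies after quantization.
    compression
        Midrange-compression factor tau of the histogram transform
        ``u = Phi(z / tau)``; tau > 1 concentrates intensity mass in the
        middle of the range (lowering entropy) without creating an edge
        spike. Applied before the power transform.
    decorrelation
        Fraction of VOI voxels whose values are randomly permuted among
        themselves (thermal-noise speckle). Leaves the intensity histogram
        untouched while destroying local spatial correlation, so it moves
        co-occurrence statistics without moving marginal ones.
    posterization
        Number of discrete intensity plateaus the rim is rounded to
        (0 = off, continuous). Mimics tissue-level homogeneity: strongly
        lowers texture entropy while leaving the mean and spread of the
        histogram — and hence sum average, variance and contrast — nearly
        unchanged.
    background, background_noise_sd
        Mean and noise of the voxels outside the mask (never analysed).
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    semi_axes: tuple[float, float, float] = (15.0, 13.0, 8.0)
    texture_class: str = "heterogeneous"
    granularity: float = 1.1
    histogram_shape: float = 0.55
    noise_sd: float = 0.15
    core_fraction: float = 0.2
    core_quantile: float = 0.8
    core_noise_sd: float = 0.01
    compression: float = 1.0
    decorrelation: float = 0.05
    posterization: float = 0.0
    background: float = 120.0
    background_noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.texture_class not in ("heterogeneous", "homogeneous"):
            raise ValueError(f"unknown texture_class {self.texture_class!r}")
        if self.granularity <= 0:
            raise ValueError("granularity must be > 0")
        if self.histogram_shape <= 0:
            raise ValueError("histogram_shape (gamma) must be > 0")
        if self.compression <= 0:
            raise ValueError("compression (tau) must be > 0")
        if not 0 <= self.core_fraction <= 0.9:
            raise ValueError("core_fraction must be in [0, 0.9]")
        if not 0 <= self.decorrelation <= 1:
            raise ValueError("decorrelation must be in [0, 1]")
        if self.posterization < 0:
            raise ValueError("posterization must be >= 0 (0 disables)")
        center = tuple(n / 2 for n in self.shape)
        for ax, (c, n) in zip(self.semi_axes, zip(center, self.shape)):
            if ax <= 0 or ax >= min(c, n - c):
                raise ValueError(
                    f"ellipsoid semi-axes {self.semi_axes} do not fit inside "
                    f"grid {self.shape}"
                )


def _ellipsoid(shape, semi_axes, scale=1.0) -> np.ndarray:
    center = [(n - 1) / 2 for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(
        ((g - c) / (a * scale)) ** 2
        for g, c, a in zip(grids, center, semi_axes)
    )
    return r2 <= 1.0


def make_phantom(
    spec: PhantomSpec, subject_id: str = "", group_label: str | None = None
) -> VolumeWithMask:
    """Generate one lesion phantom; identical specs give identical volumes."""
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid(spec.shape, spec.semi_axes)

    if spec.granularity >= max(spec.shape):
        # smoothing limit of an infinite kernel: the field collapses to its
        # mean, i.e. a textureless lesion
        z = np.zeros(spec.shape)
    else:
        field_ = rng.normal(size=spec.shape)
        field_ = ndimage.gaussian_filter(field_, sigma=spec.granularity)
        inside = field_[mask]
        z = (field_ - inside.mean()) / max(inside.std(), 1e-12)
    # monotone histogram transform: midrange compression, then power tilt
    u = stats.norm.cdf(z / spec.compression)
    texture = u**spec.histogram_shape

    volume = np.full(spec.shape, spec.background, dtype=np.float64)
    volume += rng.normal(0.0, spec.background_noise_sd, size=spec.shape)

    rim_vals = texture[mask]
    scale = 1000.0  # plausible T2 intensity range
    lesion = texture * scale
    lesion += rng.normal(0.0, spec.noise_sd * max(rim_vals.std(), 1e-12) * scale,
                         size=spec.shape)
    volume[mask] = lesion[mask]

    if spec.posterization >= 1:
        v = volume[mask]
        lo, hi = v.min(), v.max()
        if hi > lo:
            p_ = float(spec.posterization)
            volume[mask] = lo + np.round((v - lo) / (hi - lo) * p_) * (hi - lo) / p_

    if spec.core_fraction > 0:
        core = _ellipsoid(spec.shape, spec.semi_axes, spec.core_fraction ** (1 / 3))
        core &= mask
        core_level = float(np.quantile(rim_vals, spec.core_quantile)) * scale
        volume[core] = core_level + rng.normal(
            0.0, spec.core_noise_sd * scale, size=int(core.sum())
        )

    if spec.decorrelation > 0:
        voi_idx = np.flatnonzero(mask.ravel())
        n_swap = int(round(spec.decorrelation * len(voi_idx)))
        if n_swap >= 2:
            chosen = rng.choice(voi_idx, size=n_swap, replace=False)
            flat = volume.ravel()
            flat[chosen] = flat[rng.permutation(chosen)]
            volume = flat.reshape(volume.shape)

    return VolumeWithMask(
        intensities=volume.astype(np.float32),
        spacing=spec.spacing,
        mask=mask,
        subject_id=subject_id,
        group_label=group_label,
    )


def heterogeneous_template() -> PhantomSpec:
    """AB-like class: fine-grained, upper-weighted histogram."""
    return PhantomSpec(
        texture_class="heterogeneous",
        granularity=1.6,
        histogram_shape=0.76,
        noise_sd=0.02,
        decorrelation=0.20,
        posterization=80.0,
    )


def homogeneous_template() -> PhantomSpec:
    """OKC-like class: coarse-grained, lower-weighted histogram."""
    return PhantomSpec(
        texture_class="homogeneous",
        granularity=1.6,
        histogram_shape=1.0,
        noise_sd=0.02,
        decorrelation=0.08,
        posterization=30.0,
    )


@dataclass(frozen=True)
class CohortSpec:
    """A labeled two-class cohort of phantoms.

    Defaults mirror the study design this generator stands in for: 8
    AB-like and 10 OKC-like subjects. Per-subject parameters are jittered
    around the class templates along independent axes (granularity,
    histogram shape, noise, lesion size, core fraction) so that
    within-class variance is nonzero and group comparison remains
    nontrivial.
    """

    n_ab: int = 8
    n_okc: int = 10
    ab_template: PhantomSpec = field(default_factory=heterogeneous_template)
    okc_template: PhantomSpec = field(default_factory=homogeneous_template)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ab + self.n_okc < 4:
            raise ValueError("cohort needs at least 4 subjects")


def _jitter_spec(template: PhantomSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    # independent within-class variation axes; magnitudes are part of the
    # generator's declared study conditions (see docs/methods.md)
    granularity = template.granularity * float(rng.lognormal(0.0, 0.08))
    gamma = template.histogram_shape * float(rng.lognormal(0.0, 0.11))
    tau = template.compression  # class-level setting, deliberately unjittered
    noise = template.noise_sd * float(rng.lognormal(0.0, 0.30))
    size = float(rng.uniform(0.82, 1.12))
    semi_axes = tuple(a * size for a in template.semi_axes)
    core_fraction = float(rng.uniform(0.06, 0.13))
    core_quantile = float(rng.uniform(0.52, 0.97))
    core_noise_sd = float(np.exp(rng.uniform(np.log(0.0015), np.log(0.021))))
    decorrelation = min(float(template.decorrelation * rng.lognormal(0.0, 0.68)), 0.5)
    posterization = (
        template.posterization * float(rng.lognormal(0.0, 0.35))
        if template.posterization else 0.0
    )
    return replace(
        template,
        granularity=granularity,
        histogram_shape=gamma,
        compression=tau,
        noise_sd=noise,
        semi_axes=semi_axes,
        core_fraction=core_fraction,
        core_quantile=core_quantile,
        core_noise_sd=core_noise_sd,
        decorrelation=decorrelation,
        posterization=posterization,
        seed=seed,
    )


def make_cohort(
    spec: CohortSpec | None = None,
) -> tuple[list[VolumeWithMask], pd.DataFrame]:
    """Generate the labeled cohort and its manifest.

    Returns the phantoms (AB-like first) and a manifest DataFrame recording
    per-subject seeds and jittered parameters; a fixed master seed gives an
    identical manifest and bit-identical volumes across runs.
    """
    if spec is None:
        spec = CohortSpec()
    rng = np.random.default_rng(spec.master_seed)
    phantoms: list[VolumeWithMask] = []
    records = []
    plan = [("AB", i + 1, spec.ab_template) for i in range(spec.n_ab)]
    plan += [("OKC", i + 1, spec.okc_template) for i in range(spec.n_okc)]
    for group, num, template in plan:
        subject_id = f"{group}{num:02d}"
        subject_seed = int(rng.integers(0, 2**31 - 1))
        pspec = _jitter_spec(template, rng, subject_seed)
        phantoms.append(make_phantom(pspec, subject_id=subject_id, group_label=group))
        records.append(
            {
                "subject_id": subject_id,
                "group": group,
                "seed": subject_seed,
                "texture_class": pspec.texture_class,
                "granularity": pspec.granularity,
                "histogram_shape": pspec.histogram_shape,
                "compression": pspec.compression,
                "noise_sd": pspec.noise_sd,
                "core_fraction": pspec.core_fraction,
                "core_quantile": pspec.core_quantile,
                "core_noise_sd": pspec.core_noise_sd,
                "decorrelation": pspec.decorrelation,
                "posterization": pspec.posterization,
                "semi_axis_x": pspec.semi_axes[0],
                "semi_axis_y": pspec.semi_axes[1],
                "semi_axis_z": pspec.semi_axes[2],
            }
        )
    manifest = pd.DataFrame.from_records(records).set_index("subject_id")
    return phantoms, manifest


def write_cohort(
    phantoms: list[VolumeWithMask], manifest: pd.DataFrame, outdir: str | Path
) -> Path:
    """Write NIfTI volume/mask pairs plus the manifest CSV; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    vol_paths, mask_paths = [], []
    for vwm in phantoms:
        vol = outdir / f"{vwm.subject_id}_volume.nii.gz"
        msk = outdir / f"{vwm.subject_id}_mask.nii.gz"
        write_volume_with_mask(vwm, vol, msk)
        vol_paths.append(vol.name)
        mask_paths.append(msk.name)
    manifest["volume"] = vol_paths
    manifest["mask"] = mask_paths
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path)
    return manifest_path
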