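"""Synthetic ventricle-like phantoms and simulated manual segmentations.

The study's physical chain — 3D-printed ventricular models, jelly phantoms,
MR imaging, and four trained operators tracing the lateral ventricles slice
by slice — is emulated here with voxel arithmetic:

* phantoms are unions of mirrored ellipsoid pairs (a body and a temporal
  horn per hemisphere), uniformly scaled so their volume matches a target
  (by default the certified gold values of the study subjects);
* a binary mask's volume is foreground voxels times voxel volume;
* an operator's manual segmentation is the truth mask whose boundary is
  shifted, via the Euclidean signed-distance transform, by a systematic
  bias plus smooth one-sided per-slice noise (voxels whose signed distance
  exceeds the negated offset are kept).  The noise scale is
  multiplied by a per-view factor, encoding that tracing is hardest in the
  sagittal plane and easiest in the axial plane.

The per-slice noise is folded (half-normal): slice-level tracing errors are
one-sided toward over-inclusion of ambiguous boundary voxels, which is what
makes harder views produce systematically larger volumes — not merely
noisier ones — while zero bias and zero jitter leave the mask untouched.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference

logger = logging.getLogger(__name__)

#: Slicing axis of each radiological view (0-based grid axes x, y, z).
VIEW_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}
VIEWS = tuple(VIEW_AXES)


class EmptyMaskError(ValueError):
    """A voxelization or perturbation produced an empty mask."""


class PerturbationError(ValueError):
    """Operator simulation emptied the mask."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center (mm) and semi-axes (mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.semi_axes) != 3:
            raise ValueError("center and semi_axes must be 3-vectors")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")

    @property
    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def scaled(self, s: float) -> "Ellipsoid":
        return Ellipsoid(
            tuple(c * s for c in self.center),
            tuple(a * s for a in self.semi_axes),
        )

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return (
            ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        ) <= 1.0


def union_volume(
    components: Sequence[Ellipsoid],
    n_samples: int = 400_000,
    seed: int = 20230511,
) -> float:
    """Volume (mm^3) of a union of ellipsoids.

    Exact (sum of 4/3*pi*a*b*c) when the components are pairwise disjoint by
    the bounding-sphere test; otherwise seeded Monte-Carlo integration over
    the joint bounding box (~0.3% relative error at the default sample
    count).
    """
    comps = list(components)
    if not comps:
        raise ValueError("need at least one component")
    if len(comps) == 1 or _pairwise_disjoint(comps):
        return float(sum(c.volume for c in comps))
    lo, hi = _bounding_box(comps)
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = np.zeros(n_samples, dtype=bool)
    for c in comps:
        inside |= c.contains(pts[:, 0], pts[:, 1], pts[:, 2])
    return float(inside.mean() * np.prod(hi - lo))


def _pairwise_disjoint(comps: Sequence[Ellipsoid]) -> bool:
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            ci = np.asarray(comps[i].center)
            cj = np.asarray(comps[j].center)
            if np.linalg.norm(ci - cj) < (
                max(comps[i].semi_axes) + max(comps[j].semi_axes)
            ):
                return False
    return True


def _bounding_box(comps: Sequence[Ellipsoid]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.min([np.asarray(c.center) - np.asarray(c.semi_axes) for c in comps], axis=0)
    hi = np.max([np.asarray(c.center) + np.asarray(c.semi_axes) for c in comps], axis=0)
    return lo, hi


@dataclass(frozen=True)
class PhantomSpec:
    """A phantom: ellipsoid components and their analytic union volume."""

    components: tuple[Ellipsoid, ...]
    analytic_volume: float  # mm^3
    subject_label: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("phantom needs at least one component")
        if self.analytic_volume <= 0:
            raise ValueError("analytic_volume must be > 0")


def make_phantom(
    components: Sequence[Ellipsoid], subject_label: str = ""
) -> PhantomSpec:
    return PhantomSpec(
        components=tuple(components),
        analytic_volume=union_volume(components),
        subject_label=subject_label,
    )


# Base left-hemisphere geometry, mm: an antero-posterior elongated body and
# an infero-lateral temporal horn.  The right hemisphere is its x-mirror.
_BASE_BODY = Ellipsoid((-11.0, 2.0, 2.0), (7.0, 24.0, 8.0))
_BASE_HORN = Ellipsoid((-16.0, -20.0, -6.0), (5.0, 11.0, 5.0))


def ventricle_phantom(
    subject_label: str | None = None,
    target_volume_ml: float | None = None,
    seed: int = 0,
    shape_jitter: float = 0.08,
) -> PhantomSpec:
    """Build a lateral-ventricle-like phantom of known volume.

    Either a study ``subject_label`` (target = its certified gold volume) or
    an explicit ``target_volume_ml`` must be given.  ``seed`` perturbs the
    base shape (semi-axes and horn placement) so distinct subjects are not
    rescaled copies; the union is then scaled uniformly so its analytic
    volume equals the target.
    """
    if target_volume_ml is None:
        if subject_label is None:
            raise ValueError("give a subject_label or a target_volume_ml")
        target_volume_ml = reference.gold_volume(subject_label)
    if target_volume_ml <= 0:
        raise ValueError("target volume must be positive")
    rng = np.random.default_rng(seed)

    def jit(values):
        return tuple(
            v * (1.0 + shape_jitter * rng.uniform(-1.0, 1.0)) for v in values
        )

    left = [
        Ellipsoid(jit(_BASE_BODY.center), jit(_BASE_BODY.semi_axes)),
        Ellipsoid(jit(_BASE_HORN.center), jit(_BASE_HORN.semi_axes)),
    ]
    comps = left + [
        Ellipsoid((-c.center[0], c.center[1], c.center[2]), c.semi_axes)
        for c in left
    ]
    base_volume = union_volume(comps)
    s = (target_volume_ml * 1000.0 / base_volume) ** (1.0 / 3.0)
    comps = [c.scaled(s) for c in comps]
    return PhantomSpec(
        components=tuple(comps),
        analytic_volume=target_volume_ml * 1000.0,
        subject_label=subject_label or f"{target_volume_ml:g}ml",
    )


# ---------------------------------------------------------------------------
# Binary masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryMask:
    """3D binary voxel grid with isotropic-or-not voxel spacing (mm).

    Coordinates are 0-based voxel indices; world position = index * spacing
    (no affine rotation).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        object.__setattr__(self, "grid", g.astype(bool))
        sp = tuple(float(s) for s in np.atleast_1d(self.spacing).ravel())
        if len(sp) == 1:
            sp = sp * 3
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing must be three positive lengths")
        object.__setattr__(self, "spacing", sp)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.grid.sum())


def mask_volume(mask: BinaryMask) -> float:
    """Mask volume in ml: foreground voxels x voxel volume / 1000."""
    return mask.count() * mask.voxel_volume / 1000.0


def voxelize(spec: PhantomSpec, spacing: float = 1.0) -> BinaryMask:
    """Rasterize a phantom: voxel = 1 iff its center is inside any component."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    lo, hi = _bounding_box(spec.components)
    lo, hi = lo - spacing, hi + spacing
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * spacing for d in range(3)]
    x = axes[0][:, None, None]
    y = axes[1][None, :, None]
    z = axes[2][None, None, :]
    grid = np.zeros(tuple(shape), dtype=bool)
    for comp in spec.components:
        grid |= comp.contains(x, y, z)
    if not grid.any():
        warnings.warn(
            f"phantom {spec.subject_label!r} is smaller than one voxel at "
            f"spacing {spacing} mm",
            UserWarning,
            stacklevel=2,
        )
        raise EmptyMaskError(
            f"voxelization at spacing {spacing} mm produced an empty mask"
        )
    return BinaryMask(grid=grid, spacing=(spacing,) * 3)


def signed_distance(mask: BinaryMask) -> np.ndarray:
    """Euclidean signed distance (mm): positive inside, negative outside."""
    grid = mask.grid
    inside = ndimage.distance_transform_edt(grid, sampling=mask.spacing)
    outside = ndimage.distance_transform_edt(~grid, sampling=mask.spacing)
    return inside - outside


# ---------------------------------------------------------------------------
# Operator simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatorProfile:
    """Systematic and random tracing behaviour of one human operator.

    ``bias_mm`` shifts the traced boundary outward (positive = over-
    segmentation, the dominant behaviour observed in practice);
    ``jitter_mm`` scales smooth one-sided per-slice noise, further
    multiplied by the per-view difficulty factors.
    """

    operator_id: str
    bias_mm: float = 0.0
    jitter_mm: float = 0.0
    view_factors: Mapping[str, float] = field(
        default_factory=lambda: {"axial": 1.0, "coronal": 1.6, "sagittal": 2.4}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_mm < 0:
            raise ValueError("jitter_mm must be >= 0")
        if set(self.view_factors) != set(VIEWS):
            raise ValueError(f"view_factors must cover {VIEWS}")
        if any(v <= 0 for v in self.view_factors.values()):
            raise ValueError("view_factors must all be > 0")


#: Default panel of four trained operators.  Biases are positive
#: (over-segmentation) and heterogeneous; magnitudes are calibrated so the
#: simulated study reproduces the order and percent-error range of the
#: recorded operator study, not its exact numbers.
DEFAULT_OPERATORS: tuple[OperatorProfile, ...] = (
    OperatorProfile("Op1", bias_mm=0.55, jitter_mm=0.30, seed=101),
    OperatorProfile("Op2", bias_mm=0.80, jitter_mm=0.35, seed=102),
    OperatorProfile("Op3", bias_mm=0.35, jitter_mm=0.25, seed=103),
    OperatorProfile("Op4", bias_mm=0.20, jitter_mm=0.40, seed=104),
)


def _derive_seed(profile: OperatorProfile, view: str, repeat_index: int) -> int:
    key = f"{profile.seed}|{profile.operator_id}|{view}|{repeat_index}"
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def _slice_offsets(
    n_slices: int, profile: OperatorProfile, view: str, repeat_index: int
) -> np.ndarray:
    """Boundary offset (mm) per slice along the view axis."""
    rng = np.random.default_rng(_derive_seed(profile, view, repeat_index))
    scale = profile.jitter_mm * float(profile.view_factors[view])
    if scale == 0.0:
        return np.full(n_slices, profile.bias_mm)
    raw = rng.standard_normal(n_slices)
    smooth = ndimage.gaussian_filter1d(raw, sigma=2.0, mode="nearest")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return profile.bias_mm + scale * np.abs(smooth)


def _offset_threshold(
    sdt: np.ndarray, offsets: np.ndarray, axis: int
) -> np.ndarray:
    shape = [1, 1, 1]
    shape[axis] = offsets.size
    return sdt >= -offsets.reshape(shape)


def simulate_operator_mask(
    truth: BinaryMask,
    profile: OperatorProfile,
    view: str = "axial",
    repeat_index: int = 1,
    sdt: np.ndarray | None = None,
) -> BinaryMask:
    """One simulated manual segmentation of ``truth``.

    Deterministic given (profile.seed, operator_id, view, repeat_index).
    ``sdt`` may pass a precomputed signed-distance transform of the truth
    mask (it is recomputed otherwise).
    """
    if view not in VIEW_AXES:
        raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
    if not truth.grid.any():
        raise ValueError("truth mask is empty")
    if sdt is None:
        sdt = signed_distance(truth)
    axis = VIEW_AXES[view]
    offsets = _slice_offsets(truth.grid.shape[axis], profile, view, repeat_index)
    grid = _offset_threshold(sdt, offsets, axis)
    if not grid.any():
        raise PerturbationError(
            f"operator perturbation emptied the mask "
            f"(operator={profile.operator_id}, bias={profile.bias_mm} mm, "
            f"jitter={profile.jitter_mm} mm, view={view}, "
            f"repeat={repeat_index})"
        )
    return BinaryMask(grid=grid, spacing=truth.spacing)


def simulate_study(
    subjects: Mapping[str, BinaryMask],
    profiles: Sequence[OperatorProfile] = DEFAULT_OPERATORS,
    views: Sequence[str] = VIEWS,
    n_repeats: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full manual-segmentation study.

    Every operator segments every subject ``n_repeats`` times in every view
    (3 views x 3 repeats = 9 segmentations per operator and subject, as in
    the recorded protocol).  Returns a long record table
    (subject, operator, view, repeat, volume_ml) and a gold table where the
    gold volume is the truth mask's own volume — the simulated stand-in for
    the certified automation's reading.
    """
    records, gold = [], []
    for label, truth in subjects.items():
        sdt = signed_distance(truth)
        voxvol = truth.voxel_volume
        gold.append({"subject": label, "volume_ml": mask_volume(truth)})
        for profile in profiles:
            for view in views:
                axis = VIEW_AXES[view]
                for rep in range(1, n_repeats + 1):
                    offsets = _slice_offsets(
                        truth.grid.shape[axis], profile, view, rep
                    )
                    grid = _offset_threshold(sdt, offsets, axis)
                    records.append(
                        {
                            "subject": label,
                            "operator": profile.operator_id,
                            "view": view,
                            "repeat": rep,
                            "volume_ml": grid.sum() * voxvol / 1000.0,
                        }
                    )
    return pd.DataFrame(records), pd.DataFrame(gold)


def make_study_subjects(
    labels: Sequence[str] = reference.SUBJECTS,
    spacing: float = 1.0,
    seed: int = 0,
) -> dict[str, BinaryMask]:
    """Voxelized phantoms for the named study subjects."""
    rng = np.random.default_rng(seed)
    return {
        label: voxelize(
            ventricle_phantom(subject_label=label, seed=int(rng.integers(2**31))),
            spacing=spacing,
        )
        for label in labels
    }


def make_synthetic_subjects(
    n: int,
    volume_range_ml: tuple[float, float] = (3.4, 115.9),
    spacing: float = 1.0,
    seed: int = 0,
) -> dict[str, BinaryMask]:
    """``n`` phantoms with volumes log-spaced over ``volume_range_ml``."""
    targets = np.geomspace(volume_range_ml[0], volume_range_ml[1], n)
    rng = np.random.default_rng(seed)
    return {
        f"S{i + 1:02d}": voxelize(
            ventricle_phantom(
                target_volume_ml=float(v), seed=int(rng.integers(2**31))
            ),
            spacing=spacing,
        )
        for i, v in enumerate(targets)
    }


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as NIfTI-1; spacing goes into the voxel dims."""
    import nibabel as nib

    affine = np.diag([*mask.spacing, 1.0])
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    """Read a NIfTI-1 mask; non-binary data are thresholded at 0.5."""
    import nibabel as nib

    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt header or payload
        raise OSError(f"cannot read NIfTI mask {path}: {exc}") from exc
    if data.ndim != 3:
        raise OSError(f"expected a 3-D mask, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if len(set(np.round(zooms, 6))) > 1:
        logger.info("anisotropic spacing %s accepted for %s", zooms, path)
    values = np.unique(data)
    if not np.all(np.isin(values, (0, 1))):
        logger.warning(
            "non-binary image %s binarized at threshold 0.5 "
            "(value range [%g, %g])", path, data.min(), data.max()
        )
    return BinaryMask(grid=data > 0.5, spacing=zooms)


__all__ = [
    "VIEW_AXES", "VIEWS", "EmptyMaskError", "PerturbationError", "Ellipsoid",
    "union_volume", "PhantomSpec", "make_phantom", "ventricle_phantom",
    "BinaryMask", "mask_volume", "voxelize", "signed_distance",
    "OperatorProfile", "DEFAULT_OPERATORS", "simulate_operator_mask",
    "simulate_study", "make_study_subjects", "make_synthetic_subjects",
    "write_mask", "read_mask",
]
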