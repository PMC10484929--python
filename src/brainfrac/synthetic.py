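"""Synthetic imaging phantoms with exact ground truth.

Everything downstream (registration, atlas interpolation, voxel
classification, 2D counting, group statistics) is exercised on data from
this module, so every generator is seed-deterministic and returns the exact
truth next to the images.

The 3D phantom is an ellipsoidal "brain" partitioned into 7 connected
regions (a two-part core plus five angular shell sectors, named after the
regions of a neonatal mouse brain). The stained signal is a field of
isotropic Gaussian intensity blobs planted region by region until each
region's positive-voxel fraction — voxels where the noise-free blob field
exceeds half the blob amplitude — reaches its requested target. Both
channels carry additive Gaussian noise; the autofluorescence channel shows
the brain body only.

The default blob amplitude (6x the noise sigma) ties the truth definition
(half-maximum contour) to the measurement chain: it is calibrated by
simulation so that the full classification chain (percentile noise-sigma
estimate, slicewise band-pass, 2-sigma threshold) recovers the planted
volume fraction at the median staining density of the modeled study. The
calibration and its residual density dependence are described in the
methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.measure import perimeter_crofton

from .atlas import Atlas, SliceAnnotation
from .types import ImageStack

__all__ = [
    "REGION_NAMES",
    "PhantomSpec3D",
    "PhantomSpec2D",
    "PlantedCell",
    "GroundTruth3D",
    "make_phantom_atlas",
    "generate_brain_volume",
    "generate_annotation_stack",
    "generate_cortex_slice",
    "generate_group_experiment",
    "reference_landmarks",
    "study_fractions",
]

#: the seven segmented regions (id = index + 1)
REGION_NAMES = (
    "myelencephalon",
    "metencephalon/midbrain",
    "diencephalon",
    "hippocampus",
    "neocortex",
    "striatum",
    "cerebellum",
)

#: angular width (degrees) of each shell sector, chosen so the neocortex is
#: the largest region as in a real neonatal brain
_SECTOR_DEG = {
    "myelencephalon": 55.0,
    "metencephalon/midbrain": 60.0,
    "neocortex": 140.0,
    "striatum": 50.0,
    "cerebellum": 55.0,
}
_CORE_RHO = 0.45  # elliptical radius separating core from shell


def region_table() -> pd.DataFrame:
    return pd.DataFrame(
        {"id": range(1, len(REGION_NAMES) + 1), "name": list(REGION_NAMES)}
    )


@dataclass(frozen=True)
class PhantomSpec3D:
    """Specification of one 3D two-channel brain phantom."""

    shape_vx: tuple[int, int, int] = (96, 128, 128)
    spacing_um: tuple[float, float, float] = (3.5, 5.0, 5.0)
    brain_semiaxes_vx: tuple[float, float, float] = (36.0, 52.0, 52.0)
    region_count: int = 7
    region_fractions: tuple[tuple[int, float], ...] = ()
    blob_sigma_vx: float = 2.0
    blob_amplitude: float = 60.0
    background_level: float = 200.0
    background_gradient: tuple[float, float, float] = (0.0, 0.0, 0.05)
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        ids = {rid for rid, _ in self.region_fractions}
        if not ids <= set(range(1, self.region_count + 1)):
            raise ValueError("region_fractions keys must be valid region ids")
        if any(not 0 <= f <= 1 for _, f in self.region_fractions):
            raise ValueError("region fractions must lie in [0, 1]")
        for s, a in zip(self.shape_vx, self.brain_semiaxes_vx):
            if a <= 0 or 2 * a > s:
                raise ValueError("ellipsoid must fit inside the volume")

    def fractions_dict(self) -> dict[int, float]:
        return dict(self.region_fractions)

    def with_fractions(self, fractions: dict[int, float]) -> "PhantomSpec3D":
        return replace(self, region_fractions=tuple(sorted(fractions.items())))


@dataclass
class GroundTruth3D:
    """Exact ground truth of a generated 3D phantom."""

    atlas: Atlas
    positive_mask: np.ndarray
    region_fraction: dict[int, float]
    brain_mask: np.ndarray


# one atlas per geometry; phantom generation reuses it across a cohort
_ATLAS_CACHE: dict[tuple, Atlas] = {}


def make_phantom_atlas(spec: PhantomSpec3D) -> Atlas:
    """Partition the phantom ellipsoid into 7 connected, non-empty regions.

    The normalized elliptical radius rho splits a core (rho < 0.45) from a
    shell; the core is halved along y into diencephalon and hippocampus, and
    the shell is divided into five angular sectors in the (y, x) plane.
    """
    key = (spec.shape_vx, spec.brain_semiaxes_vx)
    if key in _ATLAS_CACHE:
        return _ATLAS_CACHE[key]
    nz, ny, nx = spec.shape_vx
    cz, cy, cx = ((n - 1) / 2.0 for n in spec.shape_vx)
    az, ay, ax = spec.brain_semiaxes_vx
    z, y, x = np.meshgrid(
        (np.arange(nz) - cz) / az,
        (np.arange(ny) - cy) / ay,
        (np.arange(nx) - cx) / ax,
        indexing="ij",
        sparse=True,
    )
    rho2 = z**2 + y**2 + x**2
    inside = rho2 <= 1.0
    labels = np.zeros(spec.shape_vx, dtype=np.int32)
    core = inside & (rho2 < _CORE_RHO**2)
    yy = np.broadcast_to(y, spec.shape_vx)
    labels[core & (yy < 0)] = REGION_NAMES.index("diencephalon") + 1
    labels[core & (yy >= 0)] = REGION_NAMES.index("hippocampus") + 1
    shell = inside & ~core
    angle = np.degrees(np.arctan2(yy, np.broadcast_to(x, spec.shape_vx))) % 360.0
    start = 0.0
    for name, width in _SECTOR_DEG.items():
        rid = REGION_NAMES.index(name) + 1
        sector = shell & (angle >= start) & (angle < start + width)
        labels[sector] = rid
        start += width
    atlas = Atlas(labels=labels, regions=region_table(), spacing_um=spec.spacing_um)
    _ATLAS_CACHE[key] = atlas
    return atlas


def _background(spec: PhantomSpec3D) -> np.ndarray:
    """Smooth background: level + per-axis linear gradient.

    The background is smooth across the brain boundary (no intensity step):
    a step at the edge would dominate the high-pass response of the signal
    channel with an artefactual bright ring. The brain body itself is
    carried by the autofluorescence channel.
    """
    nz, ny, nx = spec.shape_vx
    gz, gy, gx = spec.background_gradient
    return (
        spec.background_level
        + gz * np.arange(nz)[:, None, None]
        + gy * np.arange(ny)[None, :, None]
        + gx * np.arange(nx)[None, None, :]
    )


def generate_brain_volume(
    spec: PhantomSpec3D,
) -> tuple[ImageStack, ImageStack, GroundTruth3D]:
    """Generate one two-channel phantom with exact ground truth.

    Blobs are planted per region at random (sub-voxel) in-region centers
    until the region's positive fraction reaches its target within one blob
    volume; an unreachable target raises, naming the region. Identical specs
    (including seed) give bit-identical stacks.
    """
    rng = np.random.default_rng(spec.seed)
    atlas = make_phantom_atlas(spec)
    labels = atlas.labels
    brain = atlas.brain_mask
    region_sizes = np.bincount(labels.ravel(), minlength=spec.region_count + 1)

    signal = np.zeros(spec.shape_vx, dtype=np.float64)
    positive = np.zeros(spec.shape_vx, dtype=bool)
    pos_counts = np.zeros(spec.region_count + 1, dtype=np.int64)

    sigma = spec.blob_sigma_vx
    amp = spec.blob_amplitude
    half = amp / 2.0
    patch_r = int(math.ceil(4.0 * sigma))
    r_half = sigma * math.sqrt(2.0 * math.log(2.0))
    blob_vol = 4.0 / 3.0 * math.pi * r_half**3

    coords_by_region = {
        rid: np.argwhere(labels == rid)
        for rid, f in spec.fractions_dict().items()
        if f > 0
    }
    for rid, frac in sorted(spec.fractions_dict().items()):
        if frac == 0:
            continue
        if frac > 0.5:
            raise ValueError(
                f"requested fraction {frac} in region {atlas.region_name(rid)!r} "
                "is unreachable: above ~50% density the union of half-maximum "
                "balls stops being punctate and random placement cannot fit "
                "further distinguishable blobs"
            )
        target = int(round(frac * region_sizes[rid]))
        if target == 0:
            continue
        coords = coords_by_region[rid]
        max_blobs = max(100, int(20 * target / blob_vol))
        planted = 0
        # stop within half a blob volume of the target: unbiased rounding
        stop = target - blob_vol / 2.0
        while pos_counts[rid] < stop:
            if planted >= max_blobs:
                raise ValueError(
                    f"cannot reach fraction {frac} in region "
                    f"{atlas.region_name(rid)!r}: planted {planted} blobs, "
                    f"fraction stuck at {pos_counts[rid] / region_sizes[rid]:.4f}"
                )
            center = coords[rng.integers(len(coords))] + rng.uniform(-0.5, 0.5, 3)
            _plant_blob(signal, positive, pos_counts, labels, center, sigma, amp, half, patch_r)
            planted += 1

    # truth is defined inside the brain: blobs whose half-maximum ball bleeds
    # past the ellipsoid surface contribute intensity but not truth voxels
    positive &= brain
    region_fraction = {
        rid: pos_counts[rid] / region_sizes[rid] if region_sizes[rid] else 0.0
        for rid in range(1, spec.region_count + 1)
    }
    bg = _background(spec)
    noise_a = rng.normal(0.0, spec.noise_sigma, spec.shape_vx) if spec.noise_sigma else 0.0
    noise_b = rng.normal(0.0, spec.noise_sigma, spec.shape_vx) if spec.noise_sigma else 0.0
    # the brain body (for masking) lives in the autofluorescence channel
    autofluo = ImageStack(
        (np.where(brain, bg, 0.0) + noise_a).astype(np.float32),
        spec.spacing_um,
        "autofluo",
    )
    antibody = ImageStack(
        (bg + signal + noise_b).astype(np.float32), spec.spacing_um, "ccasp3"
    )
    truth = GroundTruth3D(
        atlas=atlas,
        positive_mask=positive,
        region_fraction=region_fraction,
        brain_mask=brain,
    )
    return autofluo, antibody, truth


def _plant_blob(signal, positive, pos_counts, labels, center, sigma, amp, half, patch_r):
    """Add one Gaussian blob and update the half-maximum truth mask and the
    per-region positive counts incrementally."""
    lo = [max(0, int(math.floor(c)) - patch_r) for c in center]
    hi = [
        min(s, int(math.floor(c)) + patch_r + 1)
        for c, s in zip(center, signal.shape)
    ]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]) - center[0],
        np.arange(lo[1], hi[1]) - center[1],
        np.arange(lo[2], hi[2]) - center[2],
        indexing="ij",
        sparse=True,
    )
    blob = amp * np.exp(-(zz**2 + yy**2 + xx**2) / (2.0 * sigma**2))
    signal[sl] += blob
    new_mask = signal[sl] > half
    gained = new_mask & ~positive[sl]
    if gained.any():
        pos_counts += np.bincount(labels[sl][gained], minlength=len(pos_counts))
        positive[sl] = new_mask


def generate_annotation_stack(
    truth: GroundTruth3D, n_slices: int, axis: int = 0
) -> list[SliceAnnotation]:
    """Sample evenly spaced annotated planes from a ground-truth atlas, for
    round-tripping through atlas interpolation."""
    extent = truth.atlas.labels.shape[axis]
    if not 2 <= n_slices <= extent:
        raise ValueError(f"need 2 <= n_slices <= {extent}, got {n_slices}")
    indices = np.unique(np.round(np.linspace(0, extent - 1, n_slices)).astype(int))
    out = []
    for idx in indices:
        sl = [slice(None)] * 3
        sl[axis] = int(idx)
        out.append(
            SliceAnnotation(
                axis=axis, plane_index=int(idx), label_image=truth.atlas.labels[tuple(sl)].copy()
            )
        )
    return out


def reference_landmarks(spec: PhantomSpec3D):
    """The phantom's canonical landmark line: along +x through the brain
    center, spanning half the x semi-axis each way."""
    from .registration import LandmarkLine

    cz, cy, cx = ((n - 1) / 2.0 for n in spec.shape_vx)
    ax = spec.brain_semiaxes_vx[2]
    return LandmarkLine(p0=(cz, cy, cx - 0.5 * ax), p1=(cz, cy, cx + 0.5 * ax))


# ---------------------------------------------------------------------------
# 2D cortex slices


@dataclass(frozen=True)
class PlantedCell:
    """One disk-shaped cell: center (row, col) px, radius px, and the set of
    channels in which it is drawn."""

    center_px: tuple[float, float]
    radius_px: float
    channels: frozenset[str]

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class PhantomSpec2D:
    """Specification of one multi-channel 2D cortex slice."""

    shape_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.645
    layer_boundaries_px: tuple[float, ...] = ()
    cells: tuple[PlantedCell, ...] = ()
    noise_sigma: float = 3.0
    background_level: float = 20.0
    cell_amplitude: float = 150.0
    min_separation_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.cells:
            r, col = c.center_px
            if not (0 <= r < self.shape_px[0] and 0 <= col < self.shape_px[1]):
                raise ValueError(f"cell center {c.center_px} outside image")


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_cortex_slice(
    spec: PhantomSpec2D,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render a multi-channel slice and its exact cell table.

    Each planted cell is a filled disk, drawn in every channel it belongs
    to, over a flat background with additive Gaussian noise. The truth table
    carries the rasterized pixel-counted area (in um^2), the rasterized
    circularity, the layer index from the supplied boundaries, and the
    channel memberships. Cells closer than their radii plus the minimum
    separation raise, keeping the truth unambiguous.
    """
    cells = spec.cells
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d = math.dist(cells[i].center_px, cells[j].center_px)
            if d < cells[i].radius_px + cells[j].radius_px + spec.min_separation_px:
                raise ValueError(
                    f"planted cells {i} and {j} are closer ({d:.1f} px) than the "
                    f"minimum separation; truth would be ambiguous"
                )
    channel_names = sorted({name for c in cells for name in c.channels})
    rng = np.random.default_rng(spec.seed)
    images = {}
    for name in channel_names:
        img = np.full(spec.shape_px, spec.background_level, dtype=np.float64)
        for c in cells:
            if name in c.channels:
                img[_disk_mask(spec.shape_px, c.center_px, c.radius_px)] = (
                    spec.background_level + spec.cell_amplitude
                )
        if spec.noise_sigma:
            img += rng.normal(0.0, spec.noise_sigma, spec.shape_px)
        images[name] = img

    b = list(spec.layer_boundaries_px)
    rows = []
    px2 = spec.pixel_size_um**2
    for c in cells:
        mask = _disk_mask(spec.shape_px, c.center_px, c.radius_px)
        area_px = int(mask.sum())
        perim = perimeter_crofton(mask)
        circ = min(1.0, 4.0 * math.pi * area_px / perim**2) if perim > 0 else 1.0
        layer = None
        if b:
            k = int(np.searchsorted(b, c.center_px[0], side="right")) - 1
            layer = f"layer_{k + 1}" if 0 <= k < len(b) - 1 else "outside"
        rows.append(
            {
                "center_row_px": c.center_px[0],
                "center_col_px": c.center_px[1],
                "radius_px": c.radius_px,
                "area_um2": area_px * px2,
                "circularity": circ,
                "layer": layer,
                "channels": ",".join(sorted(c.channels)),
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "center_row_px",
            "center_col_px",
            "radius_px",
            "area_um2",
            "circularity",
            "layer",
            "channels",
        ],
    )
    return images, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortAnimal:
    """One animal of a simulated group experiment: its group label and the
    fully resolved phantom spec (jittered fractions, own seed)."""

    animal_id: str
    group: str
    spec: PhantomSpec3D

    def generate(self):
        return generate_brain_volume(self.spec)


def generate_group_experiment(
    control_spec: PhantomSpec3D,
    treated_spec: PhantomSpec3D,
    n_control: int,
    n_treated: int,
    seed: int,
    sigma_log: float = 0.15,
) -> list[CohortAnimal]:
    """Per-animal phantom specs for a two-group experiment.

    Each animal's region fractions are the group targets multiplied by one
    lognormal factor exp(N(0, sigma_log^2)) shared across regions (animal-
    level variability in staining and exposure); each animal gets an
    independent child seed. ``sigma_log=0`` reproduces the targets exactly.
    """
    if n_control < 1 or n_treated < 1:
        raise ValueError("need at least one animal per group")
    ss = np.random.SeedSequence(seed)
    jit_rng = np.random.default_rng(ss.spawn(1)[0])
    animals = []
    for group, base, n in (("control", control_spec, n_control), ("treated", treated_spec, n_treated)):
        for i in range(n):
            factor = math.exp(jit_rng.normal(0.0, sigma_log)) if sigma_log > 0 else 1.0
            fr = {rid: min(0.9, f * factor) for rid, f in base.fractions_dict().items()}
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            animals.append(
                CohortAnimal(
                    animal_id=f"{group}_{i + 1:02d}",
                    group=group,
                    spec=replace(
                        base,
                        region_fractions=tuple(sorted(fr.items())),
                        seed=child_seed,
                    ),
                )
            )
    return animals


#: region medians of the modeled study (% of region volume / 100): the three
#: regions with a planted group effect
_EFFECT_FRACTIONS = {
    "control": {
        "neocortex": 0.00676,
        "striatum": 0.00471,
        "metencephalon/midbrain": 0.00564,
    },
    "treated": {
        "neocortex": 0.0247,
        "striatum": 0.0138,
        "metencephalon/midbrain": 0.0118,
    },
}
_WHOLE_BRAIN_TARGET = {"control": 0.00507, "treated": 0.0163}


def study_fractions(
    spec: PhantomSpec3D | None = None, effect: bool = True
) -> tuple[dict[int, float], dict[int, float]]:
    """Default per-region target fractions for the two groups.

    The three effect regions carry the study's group medians; the remaining
    regions share a common fraction solved (from the actual atlas region
    volumes) so that the volume-weighted whole-brain fraction hits the
    whole-brain group targets (0.507% control, 1.63% treated). With
    ``effect=False`` both groups get the control targets (a null cohort).
    """
    if spec is None:
        spec = PhantomSpec3D()
    atlas = make_phantom_atlas(spec)
    sizes = np.bincount(atlas.labels.ravel(), minlength=len(REGION_NAMES) + 1)
    brain = sizes[1:].sum()
    out = {}
    for group in ("control", "treated"):
        eff = _EFFECT_FRACTIONS[group]
        target = _WHOLE_BRAIN_TARGET[group]
        eff_sum = sum(sizes[REGION_NAMES.index(n) + 1] * f for n, f in eff.items())
        rest = [n for n in REGION_NAMES if n not in eff]
        rest_w = sum(sizes[REGION_NAMES.index(n) + 1] for n in rest)
        c = (target * brain - eff_sum) / rest_w
        if c < 0:
            raise ValueError("whole-brain target unreachable with the effect medians")
        fr = {REGION_NAMES.index(n) + 1: f for n, f in eff.items()}
        fr.update({REGION_NAMES.index(n) + 1: c for n in rest})
        out[group] = dict(sorted(fr.items()))
    if not effect:
        out["treated"] = dict(out["control"])
    return out["control"], out["treated"]
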