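"""Synthetic two-channel nucleus images with full ground truth.

The generator emulates interphase root-meristem nuclei as imaged by
DAPI + immunofluorescence microscopy: an elliptical nucleus with a
DAPI-dark nucleolus and bright heterochromatin blobs in the chromatin
channel, and marker foci (small Gaussian spots) in the marker channel whose
number, size, intensity and localization follow one of five activity
profiles:

* ``T1``  — foci confined to the nucleolus;
* ``T2``  — foci spread outside the nucleolus, nucleolus unlabeled;
* ``T2A`` — as T2 plus a ring of brighter foci around the nucleolus border;
* ``T2B`` — foci over the whole nucleus including the nucleolus;
* ``T3``  — foci merged into large clusters plus a minority of singletons.

Treatment conditions modulate the marker channel: hydroxyurea (``HU``)
replication arrest thins and dims the foci, and checkpoint override by
HU + caffeine (``PCC``) partially restores focus numbers while loosening
clusters so individual foci stay distinguishable.

Every generated nucleus carries a :class:`GroundTruthRecord` with the
planted masks and focus parameters, so each analysis stage can be tested by
parameter recovery.  A companion :func:`simulate_dna_content` draws gated
univariate DNA-content samples (the inverse of the cell-cycle fitter).

Reproducibility contract: the same seed and the same specification produce
bit-identical images.  Populations derive one independent RNG stream per
nucleus from ``(seed, nucleus_index)``, so parallel generation stays
reproducible.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, erosion, disk as disk_footprint

from .cellcycle import PhaseFractions
from .image import NucleusImage, save_mask_png, save_nucleus_tiff

__all__ = [
    "Condition",
    "ProfileTypeName",
    "NucleolusAppearance",
    "SyntheticNucleusSpec",
    "GeometryMasks",
    "PlantedFocus",
    "GroundTruthRecord",
    "PopulationSpec",
    "PopulationEntry",
    "PopulationResult",
    "DNAContentSample",
    "GenerationError",
    "default_spec",
    "make_geometry",
    "render_chromatin_channel",
    "plant_foci",
    "render_marker_channel",
    "generate_nucleus",
    "generate_population",
    "condition_population",
    "simulate_dna_content",
    "write_population",
    "write_dna_sample",
    "DEFAULT_LABELED_FRACTION",
    "DEFAULT_TYPE_WEIGHTS",
    "CONDITION_FOCUS_EFFECTS",
]


class GenerationError(RuntimeError):
    """Raised when a geometric constraint cannot be satisfied."""


class Condition(str, enum.Enum):
    CONTROL = "CONTROL"
    HU = "HU"
    PCC = "PCC"


class ProfileTypeName(str, enum.Enum):
    T1 = "T1"
    T2 = "T2"
    T2A = "T2A"
    T2B = "T2B"
    T3 = "T3"


class NucleolusAppearance(str, enum.Enum):
    DARK = "DARK"
    LIGHT = "LIGHT"


# Marker-channel effects of treatment: multipliers on focus count and on
# focus peak intensity.  Directions follow the observed biology (fewer and
# dimmer foci under HU; partial count restoration under PCC); magnitudes are
# free parameters of the generator.
CONDITION_FOCUS_EFFECTS: dict[Condition, tuple[float, float]] = {
    Condition.CONTROL: (1.0, 1.0),
    Condition.HU: (0.4, 0.6),
    Condition.PCC: (0.6, 0.8),
}

# Fraction of nuclei in a condition showing any marker foci (the labeling
# index / 100).  Control and HU values follow the reported measurements;
# PCC is intermediate (moderate reactivation after checkpoint override).
DEFAULT_LABELED_FRACTION: dict[Condition, float] = {
    Condition.CONTROL: 0.895,
    Condition.HU: 0.352,
    Condition.PCC: 0.60,
}

# Default mixture of activity profiles per condition.  Orderings encode the
# reported shifts: the T2A ring profile rises from under 10% (control)
# through HU to over 20% after PCC; T3 falls under HU and further under PCC;
# nucleolus-active profiles (T1, T2B) rise after PCC.
DEFAULT_TYPE_WEIGHTS: dict[Condition, dict[ProfileTypeName, float]] = {
    Condition.CONTROL: {
        ProfileTypeName.T1: 0.05,
        ProfileTypeName.T2: 0.55,
        ProfileTypeName.T2A: 0.08,
        ProfileTypeName.T2B: 0.12,
        ProfileTypeName.T3: 0.20,
    },
    Condition.HU: {
        ProfileTypeName.T1: 0.05,
        ProfileTypeName.T2: 0.55,
        ProfileTypeName.T2A: 0.15,
        ProfileTypeName.T2B: 0.12,
        ProfileTypeName.T3: 0.13,
    },
    Condition.PCC: {
        ProfileTypeName.T1: 0.10,
        ProfileTypeName.T2: 0.40,
        ProfileTypeName.T2A: 0.22,
        ProfileTypeName.T2B: 0.20,
        ProfileTypeName.T3: 0.08,
    },
}

# Nucleolar marker appearance most typical of each profile: T1 nuclei have a
# fluorescent ("light") nucleolus by definition, T2B nucleoli are frequently
# light, the remaining profiles usually show a dark nucleolus.
_DEFAULT_APPEARANCE: dict[ProfileTypeName, NucleolusAppearance] = {
    ProfileTypeName.T1: NucleolusAppearance.LIGHT,
    ProfileTypeName.T2: NucleolusAppearance.DARK,
    ProfileTypeName.T2A: NucleolusAppearance.DARK,
    ProfileTypeName.T2B: NucleolusAppearance.LIGHT,
    ProfileTypeName.T3: NucleolusAppearance.DARK,
}

# Per-condition chromatin-channel geometry: HU expands the nucleus and
# shrinks heterochromatin occupancy; PCC reverts both close to control.
_CONDITION_GEOMETRY: dict[Condition, tuple[float, float]] = {
    # (hc_target_fraction, nucleus axis scale)
    Condition.CONTROL: (0.20, 1.00),
    Condition.HU: (0.12, 1.12),
    Condition.PCC: (0.19, 1.02),
}


@dataclass
class SyntheticNucleusSpec:
    """Full parameterization of one synthetic nucleus.

    Lengths are in pixels, intensities on the 8-bit [0, 255] scale.
    ``nucleus_axes`` / ``nucleolus_axes`` are ellipse semi-axes.
    """

    profile_type: ProfileTypeName = ProfileTypeName.T2
    condition: Condition = Condition.CONTROL
    nucleolus_appearance: NucleolusAppearance = NucleolusAppearance.DARK
    shape: tuple[int, int] = (256, 256)
    nucleus_axes: tuple[float, float] = (85.0, 65.0)
    nucleolus_axes: tuple[float, float] = (24.0, 19.0)
    orientation_jitter_deg: float = 20.0
    hc_blob_count: int = 12
    hc_target_fraction: float = 0.20
    focus_count: int = 30
    focus_radius_px: float = 3.0
    focus_intensity: float = 180.0
    ring_focus_count: int = 12
    ring_intensity_boost: float = 1.5
    cluster_count: int = 3
    cluster_span_px: float = 25.0
    linear_formation_count: int = 0
    poisson_counts: bool = False  # draw focus_count ~ Poisson(mean) per nucleus
    background_level: float = 8.0
    noise_sd: float = 0.0
    # chromatin-channel rendering levels (0 = no chromatin, 255 = highly
    # condensed chromatin)
    nucleoplasm_level: float = 120.0
    hc_level: float = 200.0
    nucleolus_level: float = 60.0
    light_nucleolus_boost: float = 30.0
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        self.profile_type = ProfileTypeName(self.profile_type)
        self.condition = Condition(self.condition)
        self.nucleolus_appearance = NucleolusAppearance(self.nucleolus_appearance)
        if min(self.nucleus_axes) <= 0 or min(self.nucleolus_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if (
            self.nucleolus_axes[0] >= self.nucleus_axes[0]
            or self.nucleolus_axes[1] >= self.nucleus_axes[1]
        ):
            raise ValueError("nucleolus axes must be strictly smaller than nucleus axes")
        if not (0.0 <= self.hc_target_fraction <= 0.6):
            raise ValueError("hc_target_fraction must lie in [0, 0.6]")
        for name in ("focus_intensity", "background_level", "nucleoplasm_level",
                     "hc_level", "nucleolus_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.focus_count < 0 or self.ring_focus_count < 0:
            raise ValueError("focus counts must be non-negative")
        if (
            self.profile_type is ProfileTypeName.T2A
            and self.focus_count < self.ring_focus_count
        ):
            raise ValueError("T2A requires focus_count >= ring_focus_count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_spec(
    profile_type: ProfileTypeName | str,
    condition: Condition | str = Condition.CONTROL,
    appearance: NucleolusAppearance | str | None = None,
    **overrides,
) -> SyntheticNucleusSpec:
    """Spec with per-profile and per-condition defaults applied.

    Profile-specific focus counts/sizes are free parameters chosen to look
    realistic at the default 256 px image scale; the treatment condition
    sets heterochromatin occupancy and nucleus size (chromatin channel) and
    is applied to focus count/intensity at planting time.
    """
    ptype = ProfileTypeName(profile_type)
    cond = Condition(condition)
    app = (
        NucleolusAppearance(appearance)
        if appearance is not None
        else _DEFAULT_APPEARANCE[ptype]
    )
    hc_frac, axis_scale = _CONDITION_GEOMETRY[cond]
    per_type: dict[str, object] = {
        ProfileTypeName.T1: dict(focus_count=5, focus_radius_px=3.2),
        ProfileTypeName.T2: dict(focus_count=30),
        ProfileTypeName.T2A: dict(focus_count=34, ring_focus_count=12),
        ProfileTypeName.T2B: dict(focus_count=30),
        ProfileTypeName.T3: dict(focus_count=28, cluster_count=3, cluster_span_px=25.0),
    }[ptype]
    kwargs: dict = dict(
        profile_type=ptype,
        condition=cond,
        nucleolus_appearance=app,
        hc_target_fraction=hc_frac,
        nucleus_axes=(85.0 * axis_scale, 65.0 * axis_scale),
    )
    kwargs.update(per_type)
    kwargs.update(overrides)
    return SyntheticNucleusSpec(**kwargs)


@dataclass
class GeometryMasks:
    """Boolean nucleus / nucleolus / heterochromatin masks (same shape)."""

    nucleus: np.ndarray
    nucleolus: np.ndarray
    hc: np.ndarray

    def __post_init__(self) -> None:
        if not (self.nucleus.shape == self.nucleolus.shape == self.hc.shape):
            raise ValueError("mask shapes differ")


@dataclass
class PlantedFocus:
    """Ground-truth parameters of one planted marker focus."""

    row: float
    col: float
    radius: float
    peak: float
    kind: str = "base"  # base | ring | cluster | singleton | linear
    cluster_id: int | None = None


@dataclass
class GroundTruthRecord:
    """Per-nucleus planted parameters for recovery testing."""

    nucleus_id: int
    profile_type: ProfileTypeName
    condition: Condition
    nucleolus_appearance: NucleolusAppearance
    labeled: bool
    foci: list[PlantedFocus]
    nucleus_mask: np.ndarray
    nucleolus_mask: np.ndarray
    hc_mask: np.ndarray
    hc_target_fraction: float
    degenerate_ring: bool = False
    spec: SyntheticNucleusSpec | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.labeled != bool(self.foci):
            raise ValueError("labeled flag must match presence of planted foci")
        for f in self.foci:
            if not self.nucleus_mask[int(round(f.row)), int(round(f.col))]:
                raise ValueError("planted focus centroid outside nucleus mask")

    def to_row(self) -> dict:
        return {
            "nucleus_id": self.nucleus_id,
            "profile_type": self.profile_type.value,
            "condition": self.condition.value,
            "nucleolus_appearance": self.nucleolus_appearance.value,
            "labeled": self.labeled,
            "n_foci": len(self.foci),
            "hc_target_fraction": self.hc_target_fraction,
            "hc_actual_fraction": float(self.hc_mask.sum()) / float(self.nucleus_mask.sum()),
            "nucleus_area_px": int(self.nucleus_mask.sum()),
            "nucleolus_area_px": int(self.nucleolus_mask.sum()),
            "degenerate_ring": self.degenerate_ring,
        }


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    rotation_deg: float,
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(
        center[0],
        center[1],
        semi_axes[0],
        semi_axes[1],
        shape=shape,
        rotation=math.radians(rotation_deg),
    )
    mask[rr, cc] = True
    return mask


def make_geometry(spec: SyntheticNucleusSpec, seed=0) -> GeometryMasks:
    """Place nucleus, nucleolus and heterochromatin blobs.

    Heterochromatin disks are added by rejection sampling until the planted
    HC pixel fraction is within 0.01 of ``hc_target_fraction`` (the last
    blob is trimmed to land inside the tolerance); running out of placement
    attempts raises :class:`GenerationError` rather than undershooting
    silently.
    """
    rng = _rng(seed)
    shape = spec.shape
    center = (shape[0] / 2.0, shape[1] / 2.0)
    tilt = float(rng.uniform(-spec.orientation_jitter_deg, spec.orientation_jitter_deg))
    nucleus = _ellipse_mask(shape, center, spec.nucleus_axes, tilt)
    if not nucleus.any():
        raise GenerationError("nucleus ellipse does not intersect the image")

    inner = erosion(nucleus, disk_footprint(3))
    nucleolus = None
    for _ in range(30):
        jitter = rng.uniform(-8, 8, size=2)
        cand = _ellipse_mask(
            shape,
            (center[0] + jitter[0], center[1] + jitter[1]),
            spec.nucleolus_axes,
            tilt + float(rng.uniform(-10, 10)),
        )
        if cand.any() and not (cand & ~inner).any():
            nucleolus = cand
            break
    if nucleolus is None:
        raise GenerationError("could not place nucleolus strictly inside nucleus")

    hc = np.zeros(shape, dtype=bool)
    nucleus_area = int(nucleus.sum())
    target_px = int(round(spec.hc_target_fraction * nucleus_area))
    tol_px = max(1, int(0.01 * nucleus_area))
    if target_px > 0:
        domain = nucleus & ~dilation(nucleolus, disk_footprint(2))
        coords = np.argwhere(domain)
        if coords.size == 0:
            raise GenerationError("no room for heterochromatin outside the nucleolus")
        r_blob = math.sqrt(target_px / (math.pi * max(spec.hc_blob_count, 1)))
        attempts = 0
        while target_px - int(hc.sum()) > tol_px:
            attempts += 1
            if attempts > 5000:
                raise GenerationError(
                    f"heterochromatin placement failed: reached {hc.sum()} px "
                    f"of target {target_px} after {attempts} attempts"
                )
            deficit = target_px - int(hc.sum())
            radius = min(
                r_blob * float(rng.uniform(0.7, 1.3)),
                max(1.2, math.sqrt(deficit / math.pi)),
            )
            cy, cx = coords[rng.integers(len(coords))]
            rr, cc = draw_disk((cy, cx), radius, shape=shape)
            new = np.zeros(shape, dtype=bool)
            new[rr, cc] = True
            new &= domain & ~hc
            n_new = int(new.sum())
            if n_new == 0:
                continue
            if n_new > deficit:
                # trim the blob from the outside in so it stays compact
                pts = np.argwhere(new)
                d2 = (pts[:, 0] - cy) ** 2 + (pts[:, 1] - cx) ** 2
                keep = pts[np.argsort(d2, kind="stable")[:deficit]]
                new = np.zeros(shape, dtype=bool)
                new[keep[:, 0], keep[:, 1]] = True
            hc |= new
    return GeometryMasks(nucleus=nucleus, nucleolus=nucleolus, hc=hc)


def _sensor_noise(
    rng: np.random.Generator, sd: float, shape: tuple[int, int]
) -> np.ndarray:
    """Gaussian sensor noise truncated at +/- 3.9 sd.

    Truncation clips only the 1e-4 tail but gives every rendered channel a
    hard guarantee: no pixel strays more than 4 sd from its noiseless
    value, so background stays below ``background_level + 4 * noise_sd``.
    """
    return np.clip(rng.normal(0.0, sd, size=shape), -3.9 * sd, 3.9 * sd)


def render_chromatin_channel(
    masks: GeometryMasks, spec: SyntheticNucleusSpec, seed=0
) -> np.ndarray:
    """Render the chromatin (DAPI-like) channel as an 8-bit grid.

    Background sits at ``background_level``, nucleoplasm at mid intensity,
    heterochromatin high, and the nucleolus darker than nucleoplasm.
    """
    rng = _rng(seed)
    canvas = np.full(spec.shape, spec.background_level, dtype=float)
    canvas[masks.nucleus] = spec.nucleoplasm_level
    canvas[masks.nucleolus] = spec.nucleolus_level
    canvas[masks.hc] = spec.hc_level
    if spec.noise_sd > 0:
        canvas += _sensor_noise(rng, spec.noise_sd, spec.shape)
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def _sample_positions(
    allowed: np.ndarray,
    n: int,
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 4000,
) -> list[tuple[float, float]]:
    """Dart-throwing placement with a soft minimum-separation constraint."""
    coords = np.argwhere(allowed)
    if coords.size == 0:
        raise GenerationError("no admissible pixels for focus placement")
    placed: list[tuple[float, float]] = []
    sep2 = min_sep * min_sep
    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        y, x = coords[rng.integers(len(coords))]
        yf = float(y) + float(rng.uniform(-0.4, 0.4))
        xf = float(x) + float(rng.uniform(-0.4, 0.4))
        if all((yf - p[0]) ** 2 + (xf - p[1]) ** 2 >= sep2 for p in placed):
            placed.append((yf, xf))
    while len(placed) < n:  # relax separation if the region is crowded
        y, x = coords[rng.integers(len(coords))]
        placed.append((float(y), float(x)))
    return placed


def _jittered_focus(
    pos: tuple[float, float],
    spec: SyntheticNucleusSpec,
    intensity_scale: float,
    rng: np.random.Generator,
    kind: str = "base",
    cluster_id: int | None = None,
) -> PlantedFocus:
    radius = spec.focus_radius_px * float(rng.uniform(0.8, 1.25))
    peak = spec.focus_intensity * intensity_scale * float(rng.uniform(0.85, 1.15))
    return PlantedFocus(
        row=pos[0],
        col=pos[1],
        radius=max(radius, 1.0),
        peak=float(np.clip(peak, 20.0, 255.0)),
        kind=kind,
        cluster_id=cluster_id,
    )


def _annulus_width(nucleolus_area: float, factor: float = 0.15, minimum: float = 3.0) -> float:
    r_eq = math.sqrt(nucleolus_area / math.pi)
    return max(minimum, factor * r_eq)


def _nucleolus_boundary_radius(
    nucleolus: np.ndarray, centroid: tuple[float, float], angle: float
) -> float:
    """Distance from the nucleolus centroid to its boundary along ``angle``."""
    dy, dx = math.sin(angle), math.cos(angle)
    r = 0.0
    h, w = nucleolus.shape
    while True:
        y = int(round(centroid[0] + r * dy))
        x = int(round(centroid[1] + r * dx))
        if not (0 <= y < h and 0 <= x < w) or not nucleolus[y, x]:
            return r
        r += 0.5


def plant_foci(
    masks: GeometryMasks, spec: SyntheticNucleusSpec, seed=0
) -> tuple[list[PlantedFocus], bool]:
    """Choose ground-truth focus positions/sizes/intensities for one nucleus.

    Placement is profile-specific (see module docstring).  The treatment
    condition scales focus count and peak intensity by
    :data:`CONDITION_FOCUS_EFFECTS`.  Returns the planted foci and a flag
    marking a degenerate (under-populated, < 4 foci) perinucleolar ring.
    """
    rng = _rng(seed)
    count_mult, intensity_mult = CONDITION_FOCUS_EFFECTS[spec.condition]
    if spec.focus_count:
        mean_count = spec.focus_count * count_mult
        if spec.poisson_counts:
            n_total = max(1, int(rng.poisson(mean_count)))
        else:
            n_total = max(1, int(round(mean_count)))
    else:
        n_total = 0
    if n_total == 0:
        return [], False
    ptype = spec.profile_type
    margin = int(math.ceil(spec.focus_radius_px)) + 1
    nucleus_core = erosion(masks.nucleus, disk_footprint(margin))
    if not nucleus_core.any():
        nucleus_core = masks.nucleus
    nucleolus_dilated = dilation(masks.nucleolus, disk_footprint(margin))
    # detected footprints extend ~1.5x the nominal radius, so keep centers
    # at least 3 radii apart to avoid accidental merging of singletons
    min_sep = 3.0 * spec.focus_radius_px + 2.0
    foci: list[PlantedFocus] = []
    degenerate_ring = False

    if ptype is ProfileTypeName.T1:
        region = erosion(masks.nucleolus, disk_footprint(max(margin - 1, 1)))
        if not region.any():
            region = masks.nucleolus
        for pos in _sample_positions(region, n_total, min_sep, rng):
            foci.append(_jittered_focus(pos, spec, intensity_mult, rng))

    elif ptype in (ProfileTypeName.T2, ProfileTypeName.T2A):
        n_ring = 0
        if ptype is ProfileTypeName.T2A:
            n_ring = max(2, int(round(spec.ring_focus_count * count_mult)))
            n_ring = min(n_ring, n_total)
            if n_ring < 4:
                degenerate_ring = True
                warnings.warn(
                    "T2A ring has fewer than 4 foci; generating a degenerate ring",
                    stacklevel=2,
                )
        region = nucleus_core & ~nucleolus_dilated
        n_base = n_total - n_ring
        if n_base > 0:
            for pos in _sample_positions(region, n_base, min_sep, rng):
                foci.append(_jittered_focus(pos, spec, intensity_mult, rng))
        if n_ring:
            centroid = ndi.center_of_mass(masks.nucleolus)
            width = _annulus_width(float(masks.nucleolus.sum()))
            phase = float(rng.uniform(0, 2 * math.pi))
            h, w_img = masks.nucleus.shape
            for i in range(n_ring):
                angle = phase + 2 * math.pi * (i + float(rng.uniform(-0.25, 0.25))) / n_ring
                r_b = _nucleolus_boundary_radius(masks.nucleolus, centroid, angle)
                rr = r_b + width / 2.0 + float(rng.uniform(-0.5, 0.5))
                y = centroid[0] + rr * math.sin(angle)
                x = centroid[1] + rr * math.cos(angle)
                y = float(np.clip(y, 0, h - 1))
                x = float(np.clip(x, 0, w_img - 1))
                if not masks.nucleus[int(round(y)), int(round(x))]:
                    continue
                f = _jittered_focus((y, x), spec, intensity_mult, rng, kind="ring")
                f.peak = float(min(f.peak * spec.ring_intensity_boost, 250.0))
                foci.append(f)

    elif ptype is ProfileTypeName.T2B:
        for pos in _sample_positions(nucleus_core, n_total, min_sep, rng):
            foci.append(_jittered_focus(pos, spec, intensity_mult, rng))

    elif ptype is ProfileTypeName.T3:
        n_clustered = int(round(0.8 * n_total))
        n_singletons = n_total - n_clustered
        n_clusters = max(1, spec.cluster_count)
        span = spec.cluster_span_px
        seed_margin = int(math.ceil(span / 2)) + margin
        seed_region = erosion(masks.nucleus, disk_footprint(seed_margin)) & ~nucleolus_dilated
        if not seed_region.any():
            seed_region = nucleus_core & ~nucleolus_dilated
        seeds = _sample_positions(seed_region, n_clusters, span, rng)
        per_cluster = max(4, int(math.ceil(n_clustered / n_clusters)))
        # PCC loosens clusters: members keep enough separation that each
        # focus stays individually distinguishable; otherwise members grow
        # as a connected chain so each cluster renders as one merged blob.
        loose = spec.condition is Condition.PCC
        step = 2.5 * spec.focus_radius_px if loose else 1.2 * spec.focus_radius_px
        for ci, (sy, sx) in enumerate(seeds):
            placed: list[tuple[float, float]] = [(sy, sx)]
            tries = 0
            while len(placed) < per_cluster and tries < 500:
                tries += 1
                py, px = placed[rng.integers(len(placed))]
                ang = float(rng.uniform(0, 2 * math.pi))
                y = py + step * float(rng.uniform(0.9, 1.3)) * math.sin(ang)
                x = px + step * float(rng.uniform(0.9, 1.3)) * math.cos(ang)
                iy, ix = int(round(y)), int(round(x))
                if (y - sy) ** 2 + (x - sx) ** 2 > (span / 2.0) ** 2:
                    continue
                if not (
                    0 <= iy < masks.nucleus.shape[0]
                    and 0 <= ix < masks.nucleus.shape[1]
                    and masks.nucleus[iy, ix]
                    and not masks.nucleolus[iy, ix]
                ):
                    continue
                if loose and any(
                    (y - p[0]) ** 2 + (x - p[1]) ** 2 < step**2 for p in placed
                ):
                    continue
                if not loose and any(
                    (y - p[0]) ** 2 + (x - p[1]) ** 2 < (0.8 * step) ** 2 for p in placed
                ):
                    continue
                placed.append((y, x))
            for pos in placed:
                foci.append(
                    _jittered_focus(pos, spec, intensity_mult, rng, kind="cluster", cluster_id=ci)
                )
        if n_singletons > 0:
            region = nucleus_core & ~nucleolus_dilated
            for pos in _sample_positions(region, n_singletons, min_sep, rng):
                foci.append(_jittered_focus(pos, spec, intensity_mult, rng, kind="singleton"))

    # optional rare linear formations: 2-5 collinear foci outside the
    # nucleolus with near-touching spacing
    for _ in range(spec.linear_formation_count):
        k = int(rng.integers(2, 6))
        spacing = 2.2 * spec.focus_radius_px
        region = nucleus_core & ~nucleolus_dilated
        coords = np.argwhere(region)
        for _attempt in range(50):
            y0, x0 = coords[rng.integers(len(coords))]
            ang = float(rng.uniform(0, math.pi))
            pts = [
                (y0 + i * spacing * math.sin(ang), x0 + i * spacing * math.cos(ang))
                for i in range(k)
            ]
            ok = all(
                0 <= int(round(y)) < region.shape[0]
                and 0 <= int(round(x)) < region.shape[1]
                and region[int(round(y)), int(round(x))]
                for y, x in pts
            )
            if ok:
                for pos in pts:
                    foci.append(_jittered_focus(pos, spec, intensity_mult, rng, kind="linear"))
                break
    return foci, degenerate_ring


def render_marker_channel(
    foci: list[PlantedFocus],
    masks: GeometryMasks,
    spec: SyntheticNucleusSpec,
    seed=0,
) -> np.ndarray:
    """Render the marker channel: Gaussian spots on an autofluorescent floor.

    Each focus is an isotropic 2-D Gaussian with sd = radius / 2 whose
    centroid pixel reaches the planted peak (amplitude ``peak - background``
    above the floor).  A LIGHT nucleolus adds a diffuse elevation inside the
    nucleolus; a DARK one adds nothing.
    """
    rng = _rng(seed)
    h, w = spec.shape
    canvas = np.full((h, w), spec.background_level, dtype=float)
    if spec.nucleolus_appearance is NucleolusAppearance.LIGHT:
        canvas[masks.nucleolus] += spec.light_nucleolus_boost
    for f in foci:
        sd = max(f.radius / 2.0, 0.6)
        half = int(math.ceil(4 * sd))
        iy, ix = int(round(f.row)), int(round(f.col))
        y0, y1 = max(iy - half, 0), min(iy + half + 1, h)
        x0, x1 = max(ix - half, 0), min(ix + half + 1, w)
        if y0 >= y1 or x0 >= x1:
            raise GenerationError("planted focus outside image bounds")
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - f.row) ** 2 + (xx - f.col) ** 2
        canvas[y0:y1, x0:x1] += (f.peak - spec.background_level) * np.exp(-d2 / (2 * sd * sd))
    if spec.noise_sd > 0:
        canvas += _sensor_noise(rng, spec.noise_sd, (h, w))
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8)


def generate_nucleus(
    spec: SyntheticNucleusSpec,
    nucleus_id: int = 0,
    seed: int = 0,
    labeled: bool = True,
) -> tuple[NucleusImage, GroundTruthRecord]:
    """Generate one two-channel nucleus plus its ground truth.

    The RNG stream is derived from ``(seed, nucleus_id)``; unlabeled nuclei
    get an empty marker channel (autofluorescent floor only).
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, int(nucleus_id)])
    masks = make_geometry(spec, rng)
    chromatin = render_chromatin_channel(masks, spec, rng)
    if labeled:
        foci, degenerate = plant_foci(masks, spec, rng)
    else:
        foci, degenerate = [], False
    marker = render_marker_channel(foci, masks, spec, rng)
    image = NucleusImage(chromatin, marker, pixel_size_um=spec.pixel_size_um)
    record = GroundTruthRecord(
        nucleus_id=nucleus_id,
        profile_type=spec.profile_type,
        condition=spec.condition,
        nucleolus_appearance=spec.nucleolus_appearance,
        labeled=bool(foci),
        foci=foci,
        nucleus_mask=masks.nucleus,
        nucleolus_mask=masks.nucleolus,
        hc_mask=masks.hc,
        hc_target_fraction=spec.hc_target_fraction,
        degenerate_ring=degenerate,
        spec=spec,
    )
    return image, record


@dataclass
class PopulationEntry:
    profile_type: ProfileTypeName
    condition: Condition
    appearance: NucleolusAppearance | None
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass
class PopulationSpec:
    """Counts per (profile type, condition, appearance) plus noise/labeling."""

    entries: list[PopulationEntry]
    labeled_fraction: float = 1.0
    noise_sd: float = 0.0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.labeled_fraction <= 1.0):
            raise ValueError("labeled_fraction must lie in [0, 1]")

    @property
    def total(self) -> int:
        return sum(e.count for e in self.entries)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "labeled_fraction": self.labeled_fraction,
            "noise_sd": self.noise_sd,
            "overrides": dict(self.overrides),
            "entries": [
                {
                    "profile_type": e.profile_type.value,
                    "condition": e.condition.value,
                    "appearance": e.appearance.value if e.appearance else None,
                    "count": e.count,
                }
                for e in self.entries
            ],
        }
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PopulationSpec":
        data = yaml.safe_load(Path(path).read_text())
        entries = [
            PopulationEntry(
                profile_type=ProfileTypeName(e["profile_type"]),
                condition=Condition(e["condition"]),
                appearance=(
                    NucleolusAppearance(e["appearance"]) if e.get("appearance") else None
                ),
                count=int(e["count"]),
            )
            for e in data["entries"]
        ]
        return cls(
            entries=entries,
            labeled_fraction=float(data.get("labeled_fraction", 1.0)),
            noise_sd=float(data.get("noise_sd", 0.0)),
            overrides=dict(data.get("overrides", {})),
        )


@dataclass
class PopulationResult:
    images: list[NucleusImage]
    records: list[GroundTruthRecord]
    ground_truth: pd.DataFrame


def condition_population(
    n: int,
    condition: Condition | str,
    labeled_fraction: float | None = None,
    type_weights: dict | None = None,
    noise_sd: float = 0.0,
    **overrides,
) -> PopulationSpec:
    """Population spec for one treatment condition with its default profile mix.

    Integer per-type counts are assigned by largest-remainder rounding so
    they sum exactly to ``n``.
    """
    cond = Condition(condition)
    if labeled_fraction is None:
        labeled_fraction = DEFAULT_LABELED_FRACTION[cond]
    weights = {
        ProfileTypeName(k): float(v)
        for k, v in (type_weights or DEFAULT_TYPE_WEIGHTS[cond]).items()
    }
    total_w = sum(weights.values())
    raw = {t: n * w / total_w for t, w in weights.items()}
    counts = {t: int(math.floor(v)) for t, v in raw.items()}
    leftover = n - sum(counts.values())
    for t in sorted(raw, key=lambda t: raw[t] - counts[t], reverse=True)[:leftover]:
        counts[t] += 1
    entries = [
        PopulationEntry(profile_type=t, condition=cond, appearance=None, count=c)
        for t, c in counts.items()
        if c > 0
    ]
    return PopulationSpec(
        entries=entries,
        labeled_fraction=labeled_fraction,
        noise_sd=noise_sd,
        overrides=dict(overrides),
    )


def generate_population(pop: PopulationSpec, seed: int = 0) -> PopulationResult:
    """Generate a population of nuclei with exact labeled-count bookkeeping.

    Exactly ``round(labeled_fraction * N)`` nuclei carry foci; which nuclei
    are labeled is a seeded permutation, so the ground-truth table is
    reproducible.  ``N = 0`` yields empty outputs.
    """
    n = pop.total
    specs: list[SyntheticNucleusSpec] = []
    for entry in pop.entries:
        s = default_spec(
            entry.profile_type,
            entry.condition,
            appearance=entry.appearance,
            noise_sd=pop.noise_sd,
            **pop.overrides,
        )
        specs.extend([s] * entry.count)
    n_labeled = int(round(pop.labeled_fraction * n))
    order_rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x1AB])
    labeled_ids = set(order_rng.permutation(n)[:n_labeled].tolist()) if n else set()
    images: list[NucleusImage] = []
    records: list[GroundTruthRecord] = []
    for i, s in enumerate(specs):
        img, rec = generate_nucleus(s, nucleus_id=i, seed=seed, labeled=i in labeled_ids)
        images.append(img)
        records.append(rec)
    gt = pd.DataFrame([r.to_row() for r in records]) if records else pd.DataFrame()
    return PopulationResult(images=images, records=records, ground_truth=gt)


@dataclass
class DNAContentSample:
    """Simulated gated DNA-content events with per-event ground-truth phases."""

    events: np.ndarray
    phase_labels: np.ndarray  # 0 = G1, 1 = S, 2 = G2M
    true_fractions: PhaseFractions
    g1_mean: float
    g2_ratio: float
    cv: float

    def __post_init__(self) -> None:
        if np.any(self.events <= 0):
            raise ValueError("all events must be positive")

    def empirical_fractions(self) -> PhaseFractions:
        n = self.phase_labels.size
        return PhaseFractions(
            float(np.sum(self.phase_labels == 0)) / n,
            float(np.sum(self.phase_labels == 1)) / n,
            float(np.sum(self.phase_labels == 2)) / n,
        )


def simulate_dna_content(
    fractions: PhaseFractions,
    n: int,
    g1_mean: float = 100.0,
    g2_ratio: float = 2.0,
    cv: float = 0.05,
    seed: int = 0,
) -> DNAContentSample:
    """Draw a gated univariate DNA-content sample.

    Per event, the phase is a multinomial draw (recorded as ground truth);
    G1 events are Normal(mu, cv*mu), G2M events Normal(r*mu, cv*r*mu), and
    S events Uniform(mu, r*mu) perturbed by Normal(0, cv*mu).  Negative
    draws are resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if g2_ratio <= 1.0:
        raise ValueError("g2_ratio must exceed 1")
    if cv <= 0:
        raise ValueError("cv must be positive")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xD7A])
    labels = rng.choice(3, size=n, p=fractions.as_array())
    events = np.empty(n, dtype=float)
    g2_mean = g2_ratio * g1_mean
    for phase in range(3):
        idx = np.flatnonzero(labels == phase)
        m = idx.size
        if m == 0:
            continue
        if phase == 0:
            draw = rng.normal(g1_mean, cv * g1_mean, size=m)
        elif phase == 2:
            draw = rng.normal(g2_mean, cv * g2_mean, size=m)
        else:
            draw = rng.uniform(g1_mean, g2_mean, size=m) + rng.normal(
                0.0, cv * g1_mean, size=m
            )
        bad = draw <= 0
        while bad.any():
            k = int(bad.sum())
            if phase == 0:
                draw[bad] = rng.normal(g1_mean, cv * g1_mean, size=k)
            elif phase == 2:
                draw[bad] = rng.normal(g2_mean, cv * g2_mean, size=k)
            else:
                draw[bad] = rng.uniform(g1_mean, g2_mean, size=k) + rng.normal(
                    0.0, cv * g1_mean, size=k
                )
            bad = draw <= 0
        events[idx] = draw
    return DNAContentSample(
        events=events,
        phase_labels=labels,
        true_fractions=fractions,
        g1_mean=g1_mean,
        g2_ratio=g2_ratio,
        cv=cv,
    )


def write_population(result: PopulationResult, out_dir: str | Path, masks: bool = False) -> Path:
    """Write TIFFs, the ground-truth CSV, and (optionally) mask PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for img, rec in zip(result.images, result.records):
        save_nucleus_tiff(img, out / f"nucleus_{rec.nucleus_id:04d}.tiff")
        if masks:
            save_mask_png(rec.nucleus_mask, out / f"nucleus_{rec.nucleus_id:04d}_nucleus.png")
            save_mask_png(rec.nucleolus_mask, out / f"nucleus_{rec.nucleus_id:04d}_nucleolus.png")
            save_mask_png(rec.hc_mask, out / f"nucleus_{rec.nucleus_id:04d}_hc.png")
    result.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return out


def write_dna_sample(sample: DNAContentSample, path: str | Path) -> Path:
    """One-column event CSV with a ground-truth phase-label column."""
    path = Path(path)
    phase_names = np.array(["G1", "S", "G2M"])
    pd.DataFrame(
        {"dna_content": sample.events, "true_phase": phase_names[sample.phase_labels]}
    ).to_csv(path, index=False)
    return path
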