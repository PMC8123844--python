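"""Rule-based classification of nuclei into five marker-activity profiles.

A labeled nucleus is assigned one of five profiles from localization
features of its detected foci:

* ``T1``  — foci only inside the nucleolus;
* ``T2``  — foci spread outside a dark (marker-unlabeled) nucleolus;
* ``T2A`` — T2 plus a perinucleolar ring of brighter foci;
* ``T2B`` — foci over the whole nucleus, nucleolus included or fluorescent;
* ``T3``  — most focus area in large merged clusters.

The paper-style criteria are qualitative; each numeric threshold here is a
configurable operationalization (see :class:`ClassifierConfig`).  Rules are
applied in a fixed precedence order — cluster morphology (T3) and the
perinucleolar ring (T2A) are the most distinctive signatures, so they are
tested first — and the decision path is recorded per nucleus.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk

from .foci import FociSet, cluster_stats
from .image import NucleusImage

__all__ = [
    "ProfileType",
    "ProfileFeatures",
    "ClassifierConfig",
    "perinucleolar_annulus",
    "compute_features",
    "classify",
    "classify_fociset",
    "type_distribution",
]


class ProfileType(str, enum.Enum):
    T1 = "T1"
    T2 = "T2"
    T2A = "T2A"
    T2B = "T2B"
    T3 = "T3"
    UNLABELED = "UNLABELED"


@dataclass(frozen=True)
class ClassifierConfig:
    """Numeric operationalizations of the qualitative profile criteria.

    Each threshold encodes one phrase of the profile definitions:

    * ``t3_cluster_fraction`` — "large clusters covering the nucleus":
      minimum fraction of total focus area in merged clusters for T3.
    * ``ring_score_min`` / ``ring_focus_min`` / ``ring_intensity_min`` —
      "highly active foci forming a ring on the nucleolus perimeter":
      occupied-sector fraction, focus count, and relative brightness the
      perinucleolar annulus must reach for T2A.
    * ``t1_nucleolar_fraction`` — "foci located only within the nucleolus".
    * ``t2_nucleolar_fraction_max`` — "nucleolus is not labeled" for T2.
    * ``light_nucleolus_ratio`` — marker brightness ratio above which the
      nucleolus counts as fluorescent ("light"), which rules out T2.
    * ``n_sectors`` — angular sectors used for the ring score.
    * ``annulus_width_factor`` / ``annulus_min_width_px`` — perinucleolar
      annulus geometry, relative to the equivalent nucleolus radius.
    """

    t3_cluster_fraction: float = 0.5
    ring_score_min: float = 0.5
    ring_focus_min: int = 4
    ring_intensity_min: float = 1.0
    t1_nucleolar_fraction: float = 0.9
    t2_nucleolar_fraction_max: float = 0.05
    light_nucleolus_ratio: float = 1.2
    n_sectors: int = 12
    annulus_width_factor: float = 0.15
    annulus_min_width_px: float = 3.0
    cluster_factor: float = 5.0


@dataclass
class ProfileFeatures:
    """Localization feature vector of one labeled nucleus."""

    nucleolar_focus_fraction: float
    ring_score: float
    ring_focus_count: int
    ring_intensity_ratio: float
    large_cluster_area_fraction: float
    nucleolus_brightness_ratio: float
    nucleolus_missing: bool = False

    def __post_init__(self) -> None:
        for name in ("nucleolar_focus_fraction", "ring_score", "large_cluster_area_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


def perinucleolar_annulus(
    nucleolus_mask: np.ndarray,
    nucleus_mask: np.ndarray | None = None,
    width_factor: float = 0.15,
    min_width_px: float = 3.0,
) -> np.ndarray:
    """Ring of pixels just outside the nucleolus, clipped to the nucleus.

    Width is ``max(min_width_px, width_factor * equivalent radius)``.  An
    empty nucleolus mask raises ``ValueError`` (ring features undefined).
    """
    if not nucleolus_mask.any():
        raise ValueError("empty nucleolus mask: perinucleolar annulus undefined")
    r_eq = math.sqrt(float(nucleolus_mask.sum()) / math.pi)
    width = max(min_width_px, width_factor * r_eq)
    annulus = dilation(nucleolus_mask, disk(int(round(width)))) & ~nucleolus_mask
    if nucleus_mask is not None:
        annulus &= nucleus_mask
    return annulus


def compute_features(
    fociset: FociSet,
    nucleus_mask: np.ndarray,
    nucleolus_mask: np.ndarray,
    image: NucleusImage,
    config: ClassifierConfig = ClassifierConfig(),
) -> ProfileFeatures:
    """Compute the classification feature vector for a labeled nucleus.

    The ring score is the fraction of ``n_sectors`` equal angular sectors
    (centered at the nucleolus centroid) whose perinucleolar annulus
    contains at least one focus centroid.  With no resolvable nucleolus the
    ring and nucleolar features are zeroed and ``nucleolus_missing`` set.
    """
    if fociset.count == 0:
        raise ValueError("feature vector undefined for an empty focus set (UNLABELED)")
    marker = image.marker.astype(float)
    cs = cluster_stats(fociset, cluster_factor=config.cluster_factor)
    if not nucleolus_mask.any():
        return ProfileFeatures(
            nucleolar_focus_fraction=0.0,
            ring_score=0.0,
            ring_focus_count=0,
            ring_intensity_ratio=0.0,
            large_cluster_area_fraction=cs.large_area_fraction,
            nucleolus_brightness_ratio=float("nan"),
            nucleolus_missing=True,
        )
    nucleolar_fraction = float(np.mean([f.inside_nucleolus for f in fociset.foci]))
    annulus = perinucleolar_annulus(
        nucleolus_mask,
        nucleus_mask,
        width_factor=config.annulus_width_factor,
        min_width_px=config.annulus_min_width_px,
    )
    centroid = ndi.center_of_mass(nucleolus_mask)
    ring_foci = [
        f
        for f in fociset.foci
        if annulus[int(round(f.centroid[0])), int(round(f.centroid[1]))]
    ]
    occupied: set[int] = set()
    for f in ring_foci:
        angle = math.atan2(f.centroid[0] - centroid[0], f.centroid[1] - centroid[1])
        occupied.add(int((angle % (2 * math.pi)) / (2 * math.pi) * config.n_sectors))
    ring_score = len(occupied) / config.n_sectors
    all_mean = float(np.mean([f.mean_intensity for f in fociset.foci]))
    ring_ratio = (
        float(np.mean([f.mean_intensity for f in ring_foci])) / all_mean
        if ring_foci and all_mean > 0
        else 0.0
    )
    plain_nucleoplasm = nucleus_mask & ~nucleolus_mask & ~fociset.foci_mask()
    denom = float(marker[plain_nucleoplasm].mean()) if plain_nucleoplasm.any() else float("nan")
    numer = float(marker[nucleolus_mask].mean())
    brightness_ratio = numer / denom if denom and denom > 0 else float("inf")
    return ProfileFeatures(
        nucleolar_focus_fraction=nucleolar_fraction,
        ring_score=ring_score,
        ring_focus_count=len(ring_foci),
        ring_intensity_ratio=ring_ratio,
        large_cluster_area_fraction=cs.large_area_fraction,
        nucleolus_brightness_ratio=brightness_ratio,
    )


def classify(
    features: ProfileFeatures, config: ClassifierConfig = ClassifierConfig()
) -> tuple[ProfileType, str]:
    """Assign a profile type by the ordered decision rule.

    Precedence: T3 (clusters) → T2A (ring) → T1 (nucleolar) → T2 (dark,
    extra-nucleolar) → T2B (everything else).  Returns the type and the
    decision path actually taken.  A nucleus without a resolvable nucleolus
    can only receive T3, T2 or T2B and is flagged in the path.
    """
    path: list[str] = []
    if features.large_cluster_area_fraction >= config.t3_cluster_fraction:
        path.append(
            f"cluster_fraction {features.large_cluster_area_fraction:.2f} >= "
            f"{config.t3_cluster_fraction} -> T3"
        )
        return ProfileType.T3, "; ".join(path)
    path.append(
        f"cluster_fraction {features.large_cluster_area_fraction:.2f} < "
        f"{config.t3_cluster_fraction}"
    )
    if features.nucleolus_missing:
        path.append("nucleolus not segmented: restricted to {T2, T2B, T3} -> T2")
        return ProfileType.T2, "; ".join(path)
    if (
        features.ring_score >= config.ring_score_min
        and features.ring_focus_count >= config.ring_focus_min
        and features.ring_intensity_ratio >= config.ring_intensity_min
    ):
        path.append(
            f"ring_score {features.ring_score:.2f}, ring_count {features.ring_focus_count}, "
            f"ring_ratio {features.ring_intensity_ratio:.2f} pass -> T2A"
        )
        return ProfileType.T2A, "; ".join(path)
    path.append(f"ring_score {features.ring_score:.2f} fails ring rule")
    if features.nucleolar_focus_fraction >= config.t1_nucleolar_fraction:
        path.append(
            f"nucleolar_fraction {features.nucleolar_focus_fraction:.2f} >= "
            f"{config.t1_nucleolar_fraction} -> T1"
        )
        return ProfileType.T1, "; ".join(path)
    path.append(f"nucleolar_fraction {features.nucleolar_focus_fraction:.2f} below T1")
    if (
        features.nucleolar_focus_fraction <= config.t2_nucleolar_fraction_max
        and features.nucleolus_brightness_ratio < config.light_nucleolus_ratio
    ):
        path.append(
            f"nucleolar_fraction <= {config.t2_nucleolar_fraction_max} and dark "
            f"nucleolus (ratio {features.nucleolus_brightness_ratio:.2f}) -> T2"
        )
        return ProfileType.T2, "; ".join(path)
    path.append("-> T2B")
    return ProfileType.T2B, "; ".join(path)


def classify_fociset(
    fociset: FociSet,
    nucleus_mask: np.ndarray,
    nucleolus_mask: np.ndarray,
    image: NucleusImage,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[ProfileType, ProfileFeatures | None, str]:
    """End-to-end per-nucleus classification (UNLABELED when no foci)."""
    if fociset.count == 0:
        return ProfileType.UNLABELED, None, "no foci -> UNLABELED"
    features = compute_features(fociset, nucleus_mask, nucleolus_mask, image, config)
    ptype, path = classify(features, config)
    return ptype, features, path


def type_distribution(
    types: list[ProfileType] | pd.Series,
    conditions: list | pd.Series | None = None,
) -> pd.DataFrame:
    """Percentage of labeled nuclei per profile type, per condition.

    UNLABELED nuclei are excluded from the denominator and reported as the
    separate ``unlabeled_percent`` column (over all nuclei).  An
    all-unlabeled condition gets NaN percentages and a warning.
    """
    types = pd.Series([ProfileType(t).value for t in types], name="profile_type")
    cond = (
        pd.Series(list(conditions), name="condition")
        if conditions is not None
        else pd.Series(["ALL"] * len(types), name="condition")
    )
    df = pd.DataFrame({"condition": cond, "profile_type": types})
    out_rows = []
    order = [t.value for t in ProfileType if t is not ProfileType.UNLABELED]
    for c, grp in df.groupby("condition", sort=True):
        labeled = grp[grp.profile_type != ProfileType.UNLABELED.value]
        row = {"condition": c, "n_nuclei": len(grp), "n_labeled": len(labeled)}
        row["unlabeled_percent"] = 100.0 * (len(grp) - len(labeled)) / len(grp)
        if len(labeled) == 0:
            warnings.warn(
                f"condition {c!r} has no labeled nuclei; type distribution undefined",
                stacklevel=2,
            )
            row.update({f"{t}_percent": float("nan") for t in order})
        else:
            counts = labeled.profile_type.value_counts()
            for t in order:
                row[f"{t}_percent"] = 100.0 * counts.get(t, 0) / len(labeled)
        out_rows.append(row)
    return pd.DataFrame(out_rows)
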