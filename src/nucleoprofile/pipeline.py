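"""End-to-end orchestration: simulate or load nuclei, analyze each one,
then summarize, correlate and compare across conditions.

All outputs are plain CSV/PNG/JSON; rerunning with the same seed and
configuration reproduces the CSV contents byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import synthetic
from .cellcycle import PhaseFractions, fit_phase_model, phase_report
from .chromatin import measure_chromatin
from .config import AnalysisParams, PipelineConfig
from .foci import detect_foci, heatmap_export
from .image import NucleusImage, load_nucleus_tiff
from .profiles import ProfileType, classify_fociset, type_distribution
from .stats import compare_groups, correlate, summarize_conditions

logger = logging.getLogger("nucleoprofile")

__all__ = ["analyze_nucleus", "analyze_population", "run_pipeline"]

_CORR_PAIRS = [
    ("foci_count", "total_focus_area_px"),
    ("foci_count", "mean_focus_area_px"),
    ("foci_count", "coverage_percent"),
    ("mean_focus_area_px", "coverage_percent"),
]

_COMPARE_VARS = ["foci_count", "coverage_percent", "hc_percent", "nucleus_area_px"]


def analyze_nucleus(
    image: NucleusImage,
    params: AnalysisParams = AnalysisParams(),
    nucleus_id: int = 0,
    condition: str = "UNKNOWN",
) -> dict:
    """Run segmentation, focus detection and classification on one nucleus."""
    nucleus, nucleolus, hc, metrics = measure_chromatin(
        image,
        min_nucleus_px=params.min_nucleus_px,
        nucleolus_percentile=params.nucleolus_percentile,
        min_nucleolus_px=params.min_nucleolus_px,
        hc_fixed_threshold=params.hc_fixed_threshold,
    )
    fociset = detect_foci(
        image,
        nucleus,
        nucleolus_mask=nucleolus,
        k=params.foci_k,
        min_rise=params.foci_min_rise,
        min_focus_px=params.min_focus_px,
        threshold=params.foci_fixed_threshold,
    )
    ptype, features, path = classify_fociset(
        fociset, nucleus, nucleolus, image, params.classifier_config()
    )
    row: dict = {
        "nucleus_id": nucleus_id,
        "condition": condition,
        "nucleus_area_px": metrics.nucleus_area_px,
        "nucleolus_area_px": metrics.nucleolus_area_px,
        "hc_area_px": metrics.hc_area_px,
        "hc_percent": metrics.hc_percent,
        "labeled": fociset.labeled,
        "foci_count": fociset.count,
        "total_focus_area_px": fociset.total_area_px,
        "mean_focus_area_px": fociset.mean_area_px,
        "focus_area_sd": fociset.area_sd,
        "mean_focus_intensity": fociset.mean_intensity,
        "coverage_percent": fociset.coverage_percent,
        "profile_type": ptype.value,
        "decision_path": path,
    }
    if features is not None:
        row.update(
            {
                "nucleolar_focus_fraction": features.nucleolar_focus_fraction,
                "ring_score": features.ring_score,
                "ring_focus_count": features.ring_focus_count,
                "ring_intensity_ratio": features.ring_intensity_ratio,
                "large_cluster_area_fraction": features.large_cluster_area_fraction,
                "nucleolus_brightness_ratio": features.nucleolus_brightness_ratio,
            }
        )
    row["_fociset"] = fociset
    row["_nucleus_mask"] = nucleus
    return row


def analyze_population(
    images: list[NucleusImage],
    params: AnalysisParams = AnalysisParams(),
    conditions: list[str] | None = None,
    keep_objects: bool = False,
) -> pd.DataFrame:
    """Per-nucleus analysis table for a set of images."""
    rows = []
    for i, img in enumerate(images):
        cond = conditions[i] if conditions is not None else "UNKNOWN"
        row = analyze_nucleus(img, params, nucleus_id=i, condition=cond)
        if not keep_objects:
            row.pop("_fociset")
            row.pop("_nucleus_mask")
        logger.info("analyzed nucleus %d (%s): %s", i, cond, row["profile_type"])
        rows.append(row)
    return pd.DataFrame(rows)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path, seed: int = 0) -> Path:
    """Simulate (or load) nuclei, analyze them, and write all artifacts.

    Writes per_nucleus.csv, condition_summary.csv, type_distribution.csv,
    correlations.csv, comparisons.csv, optional cell-cycle fit reports,
    heatmap PNGs for the first nuclei, and a JSON run manifest recording
    the seed and configuration hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images: list[NucleusImage] = []
    conditions: list[str] = []

    if config.images_dir is not None:
        paths = sorted(Path(config.images_dir).glob("*.tif*"))
        if not paths:
            raise FileNotFoundError(f"no TIFF images in {config.images_dir}")
        for p in paths:
            try:
                images.append(load_nucleus_tiff(p))
            except Exception as exc:  # fail fast, naming the file
                raise RuntimeError(f"unreadable image {p}: {exc}") from exc
            conditions.append("UNKNOWN")
    elif config.simulate is not None:
        for ci, (cond_name, n) in enumerate(sorted(config.simulate.conditions.items())):
            lf = None
            if config.simulate.labeled_fraction:
                lf = config.simulate.labeled_fraction.get(cond_name)
            pop = synthetic.condition_population(
                n, cond_name, labeled_fraction=lf, noise_sd=config.simulate.noise_sd
            )
            result = synthetic.generate_population(pop, seed=(seed * 31 + ci) & 0x7FFFFFFF)
            result.ground_truth.to_csv(out / f"ground_truth_{cond_name}.csv", index=False)
            images.extend(result.images)
            conditions.extend([cond_name] * len(result.images))
    else:
        raise ValueError("config must provide either images_dir or simulate")

    table = analyze_population(images, config.analysis, conditions, keep_objects=True)
    for i in range(min(config.heatmap_count, len(images))):
        heatmap_export(images[i], table.loc[i, "_nucleus_mask"], out / f"heatmap_{i:03d}.png")
    table = table.drop(columns=["_fociset", "_nucleus_mask"])
    table.to_csv(out / "per_nucleus.csv", index=False)

    summarize_conditions(table).to_csv(out / "condition_summary.csv", index=False)
    type_distribution(
        [ProfileType(t) for t in table.profile_type], table.condition
    ).to_csv(out / "type_distribution.csv", index=False)

    corr_rows = []
    for cond, grp in table[table.labeled].groupby("condition", sort=True):
        for x, y in _CORR_PAIRS:
            try:
                res = correlate(grp[x], grp[y], x, y)
            except ValueError:
                continue
            corr_rows.append(
                {
                    "condition": cond,
                    "x": res.variable_x,
                    "y": res.variable_y,
                    "r": res.r,
                    "r_squared": res.r_squared,
                    "n": res.n,
                }
            )
    pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

    cmp_rows = []
    if table.condition.nunique() >= 2:
        for var in _COMPARE_VARS:
            try:
                gc = compare_groups(table, var)
            except ValueError:
                continue
            for _, t in gc.tukey.iterrows():
                cmp_rows.append(
                    {
                        "variable": var,
                        "anova_p": gc.anova_p,
                        "group1": t.group1,
                        "group2": t.group2,
                        "tukey_p": t.p_adj,
                        "significant": bool(t.significant),
                    }
                )
    pd.DataFrame(cmp_rows).to_csv(out / "comparisons.csv", index=False)

    if config.cellcycle is not None:
        cc = config.cellcycle
        reports = {}
        for cond_name in sorted(cc.s_fraction):
            s, g2m = cc.s_fraction[cond_name], cc.g2m_fraction[cond_name]
            sample = synthetic.simulate_dna_content(
                PhaseFractions(1.0 - s - g2m, s, g2m),
                n=cc.n_events,
                g1_mean=cc.g1_mean,
                g2_ratio=cc.g2_ratio,
                cv=cc.cv,
                seed=(seed * 131 + hash(cond_name) % 997) & 0x7FFFFFFF,
            )
            fit = fit_phase_model(sample.events)
            reports[cond_name] = phase_report(fit)
        (out / "cellcycle.json").write_text(json.dumps(reports, indent=2, sort_keys=True))

    manifest = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "n_nuclei": len(images),
        "config": config.model_dump(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
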