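"""End-to-end orchestration: images -> features -> composites -> survival.

The pipeline runs preprocessing, nuclei segmentation, nest/stroma
segmentation, nucleus classification, catalog extraction, per-patient
aggregation, composite evaluation, cutpoint categorization and KM/Cox/ROC,
and records a manifest (config, seeds, per-stage counts, output hashes)
whose hash is reproducible under a fixed seed.

In synthetic-study mode the survival times are drawn from hazards on the
*extracted*, z-standardized per-patient features, so the run exercises a
genuine image-to-outcome dependency.  Real images can be processed by
passing paths and a trained tissue classifier; without a cohort table the
survival stage is skipped with a log notice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cells, composites, features, nuclei, preprocessing, survival, synthetic
from .tissue import (
    TissueClassifier,
    classify_pixels,
    postprocess_mask,
    train_from_labeled_pixels,
)

logger = logging.getLogger(__name__)

CATALOG_VERSION = "nestquant-catalog-1"


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown keys are rejected on load."""

    seed: int = 0
    # synthetic study
    n_patients: int = 8
    images_per_patient: int = 1
    image_width: int = 192
    image_height: int = 192
    density_variation: float = 0.3  # per-patient +/- fraction on nest nuclei density
    nest_count_range: tuple[int, int] = (2, 4)
    nest_area_mean: float = 3000.0
    # preprocessing
    p_low: float = 1.0
    p_high: float = 99.0
    # nuclei segmentation
    morphology_radius: int = 2
    h_fraction: float | None = None  # None -> 10% of OD range
    min_nucleus_area: float = 30.0
    max_nucleus_area: float = 3000.0
    min_solidity: float = 0.7
    min_boundary_gradient: float = 5.0
    # tissue segmentation
    window: int = 9
    n_train_per_class: int = 400
    min_region: int = 500
    closing_radius: int = 3
    # cell classification
    ecc_round_max: float = 0.8
    # survival
    with_survival: bool = True
    betas: dict = field(default_factory=lambda: {"tns_cell_density": 0.5})
    baseline_hazard: float = 0.012
    censor_rate: float = 0.2
    follow_up_max: float = 96.0
    cutpoint_features: tuple[str, ...] = ("tns_cell_density",)
    min_group_frac: float = 0.10

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["betas"] = dict(d["betas"])
        return d


@dataclass
class PipelineResult:
    features_per_image: pd.DataFrame
    features_per_patient: pd.DataFrame
    composite_scores: pd.DataFrame
    cohort: pd.DataFrame | None
    rules: dict
    km: dict
    cox: survival.SurvivalFit | None
    roc: dict
    manifest: dict


def process_image(
    image: np.ndarray, config: PipelineConfig, classifier: TissueClassifier
) -> pd.Series:
    """Run the image stages on one RGB frame, returning its 730-feature
    vector."""
    pre = preprocessing.preprocess(image, p_low=config.p_low, p_high=config.p_high)
    stains = preprocessing.color_deconvolve(pre)
    rules = nuclei.SpuriousRules(
        min_area=config.min_nucleus_area,
        max_area=config.max_nucleus_area,
        min_solidity=config.min_solidity,
        min_boundary_gradient=config.min_boundary_gradient,
    )
    _, nucleus_objs = nuclei.segment_nuclei(
        stains.hematoxylin_od,
        morphology_radius=config.morphology_radius,
        h=None,
        rules=rules,
    )
    raw_mask = classify_pixels(pre, classifier)
    tissue_mask = postprocess_mask(raw_mask, config.min_region, config.closing_radius)
    classified = cells.classify_nuclei(nucleus_objs, tissue_mask, config.ecc_round_max)
    nests = features.tumor_nests(tissue_mask, stains.hematoxylin_od)
    nuclei_labels = _labels_from_objects(nucleus_objs, tissue_mask.shape, stains)
    return features.extract_catalog(pre, tissue_mask, nuclei_labels, classified, nests)


def _labels_from_objects(objs, shape, stains):
    # re-derive a label image for pixel-level "nuclei" region statistics
    mask = nuclei.nuclei_mask(stains.hematoxylin_od)
    markers = nuclei.extract_markers(mask, stains.hematoxylin_od)
    return nuclei.watershed_segment(markers, stains.hematoxylin_od, mask)


def _hash_df(df: pd.DataFrame) -> str:
    csv = df.to_csv(float_format="%.10g")
    return hashlib.sha256(csv.encode()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    images: list[tuple[str, str, np.ndarray]] | None = None,
    cohort: pd.DataFrame | None = None,
    classifier: TissueClassifier | None = None,
) -> PipelineResult:
    """Execute the full pipeline.

    Parameters
    ----------
    config : PipelineConfig
    out_dir : optional directory for CSV/JSON outputs.
    images : optional list of (image_id, patient_id, rgb_array); when
        omitted, a synthetic study is generated from the config.
    cohort : optional patient table with ``patient_id``, ``time``, ``event``;
        required for survival on externally supplied images.
    classifier : trained tissue classifier, required for external images.
    """
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "catalog_version": CATALOG_VERSION,
        "config": config.to_dict(),
        "stages": {},
    }

    synthetic_mode = images is None
    if synthetic_mode:
        images = []
        truths = {}
        lo, hi = config.nest_count_range
        for p in range(config.n_patients):
            density = 0.0015 * (1 + config.density_variation * (2 * rng.random() - 1))
            n_nests = int(rng.integers(lo, hi + 1))
            for i in range(config.images_per_patient):
                scen = synthetic.ImageScenario(
                    width=config.image_width,
                    height=config.image_height,
                    n_nests=n_nests,
                    nest_area_mean=config.nest_area_mean,
                    nest_area_var=(config.nest_area_mean / 4) ** 2,
                    nuclei_density_in_nest=density,
                    seed=int(config.seed * 100003 + p * 1009 + i) % (2**31),
                )
                img, truth = synthetic.generate_he_image(scen)
                image_id = f"p{p:04d}_img{i}"
                images.append((image_id, f"p{p:04d}", img))
                truths[image_id] = truth
        if classifier is None:
            first_id, _, first_img = images[0]
            sample = synthetic.generate_labeled_pixels(
                first_img, truths[first_id], config.n_train_per_class, config.seed
            )
            pre0 = preprocessing.preprocess(
                first_img, p_low=config.p_low, p_high=config.p_high
            )
            classifier = train_from_labeled_pixels(
                pre0, sample, window=config.window, seed=config.seed
            )
    elif classifier is None:
        raise ValueError("externally supplied images require a trained classifier")

    rows = {}
    patient_of = {}
    for image_id, patient_id, img in images:
        rows[image_id] = process_image(img, config, classifier)
        patient_of[image_id] = patient_id
    per_image = pd.DataFrame(rows).T
    per_image.index.name = "image_id"
    manifest["stages"]["images"] = len(per_image)

    groups = pd.Series(patient_of)
    per_patient = per_image.groupby(groups).mean()
    per_patient.index.name = "patient_id"
    manifest["stages"]["patients"] = len(per_patient)

    aliased = features.with_aliases(per_patient)
    comp_params = sorted(
        {p for spec in composites.PRINTED_COMPOSITES for p, _ in spec.terms}
    )
    comp = composites.evaluate_composites_frame(aliased[comp_params])

    cohort_df = None
    rules_out: dict = {}
    km_out: dict = {}
    cox_out = None
    roc_out: dict = {}
    if not config.with_survival or (not synthetic_mode and cohort is None):
        logger.info("no cohort available; survival stage skipped")
    else:
        if synthetic_mode:
            z = (aliased - aliased.mean()) / aliased.std(ddof=0).replace(0, np.nan)
            z = z.fillna(0.0)
            time, event = synthetic.draw_survival_times(
                z,
                config.betas,
                config.baseline_hazard,
                config.censor_rate,
                config.follow_up_max,
                rng,
            )
            cohort_df = pd.DataFrame(
                {"patient_id": per_patient.index, "time": time, "event": event}
            ).set_index("patient_id")
        else:
            cohort_df = cohort.set_index("patient_id").loc[per_patient.index]

        for feat in config.cutpoint_features:
            vals = aliased[feat].to_numpy(float)
            try:
                rule = survival.find_cutpoints(
                    vals,
                    cohort_df["time"],
                    cohort_df["event"],
                    min_group_frac=config.min_group_frac,
                    feature=feat,
                )
                rules_out[feat] = rule
                cats = rule.categorize(vals)
                if len(np.unique(cats)) >= 2:
                    km_out[feat] = survival.km_logrank(
                        cats, cohort_df["time"], cohort_df["event"]
                    )
            except ValueError as exc:
                logger.warning("cutpoint search for %s failed: %s", feat, exc)

        merged = cohort_df.join(comp)
        try:
            cox_out = survival.cox_fit(merged, list(comp.columns))
        except (ValueError, RuntimeError) as exc:
            logger.info("Cox stage skipped: %s", exc)
        try:
            roc_val, ci = survival.roc_auc(
                merged[comp.columns[0]], merged["event"]
            )
            roc_out = {"score": comp.columns[0], "auc": roc_val, "ci": ci}
        except ValueError as exc:
            logger.info("ROC stage skipped: %s", exc)

    outputs = {
        "features_per_image.csv": per_image,
        "features_per_patient.csv": per_patient,
        "composites.csv": comp,
    }
    if cohort_df is not None:
        outputs["cohort.csv"] = cohort_df
    manifest["outputs"] = {name: _hash_df(df) for name, df in outputs.items()}
    manifest["cutpoints"] = {
        f: {"c1": r.cutpoints[0], "c2": r.cutpoints[1], "chi2": round(r.statistic, 10)}
        for f, r in rules_out.items()
    }
    canonical = json.dumps(manifest, sort_keys=True, default=str)
    manifest["manifest_hash"] = hashlib.sha256(canonical.encode()).hexdigest()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in outputs.items():
            df.to_csv(out / name, float_format="%.10g")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return PipelineResult(
        features_per_image=per_image,
        features_per_patient=per_patient,
        composite_scores=comp,
        cohort=cohort_df,
        rules=rules_out,
        km=km_out,
        cox=cox_out,
        roc=roc_out,
        manifest=manifest,
    )
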