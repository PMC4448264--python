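"""Synthetic HE-like images with ground truth, and survival cohorts.

The image generator emulates the appearance a pipeline for invasive ductal
carcinoma sections must handle: irregular tumor nests of densely packed,
hematoxylin-dark epithelial nuclei embedded in eosin-pink stroma that carries
sparse round (immune-cell-like) and elongated (fibroblast/vessel-like)
nuclei.  Nuclei are rendered as hematoxylin optical-density Gaussian blobs
and the stroma as an eosin field; both are converted to RGB by Beer-Lambert
with the package's fixed stain matrix, so color deconvolution is exactly
invertible up to noise.  The only corruptions are Gaussian pixel noise and a
linear illumination gradient.

Default densities and nucleus sizes sit in the mid-range of the per-image
statistics a 200x breast-carcinoma field typically shows (epithelial nuclei
around 0.0015 per px^2 of nest, nucleus area around 200 px^2), so downstream
category boundaries for those quantities are exercised at realistic scales.

The cohort generator draws per-patient features and exponential event times
whose hazard is ``baseline * exp(sum(beta * feature))``, giving closed-form
expectations for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import draw

from .preprocessing import HE_STAIN_MATRIX, od_to_rgb

EPITHELIAL = "epithelial"
STROMAL_ROUND = "stromal_round"
STROMAL_NONROUND = "stromal_nonround"
NUCLEUS_CLASSES = (EPITHELIAL, STROMAL_ROUND, STROMAL_NONROUND)


@dataclass
class ImageScenario:
    """Parameters controlling one synthetic HE field."""

    width: int = 256
    height: int = 256
    n_nests: int = 4
    nest_area_mean: float = 5000.0  # px^2
    nest_area_var: float = 1.5e6  # px^4
    nuclei_density_in_nest: float = 0.0015  # nuclei / px^2 of nest
    stromal_round_density: float = 0.0003
    stromal_nonround_density: float = 0.00045
    nucleus_area_mean: float = 200.0  # px^2
    nucleus_area_var: float = 900.0
    nonround_eccentricity_min: float = 0.85
    stain_noise_sd: float = 3.0  # 8-bit intensity units
    illumination_gradient: float = 0.05  # total relative change across width
    seed: int = 0

    def validate(self) -> None:
        if min(self.width, self.height) < 32:
            raise ValueError("image must be at least 32 x 32")
        for name in (
            "nuclei_density_in_nest",
            "stromal_round_density",
            "stromal_nonround_density",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nest_area_mean <= 0:
            raise ValueError("nest areas must be positive")
        if not (0 <= self.nonround_eccentricity_min < 1):
            raise ValueError("eccentricity bound must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Rendering-consistent ground truth for one synthetic image."""

    nest_mask: np.ndarray  # int labels, 0 = stroma
    nuclei_mask: np.ndarray  # int labels, 0 = background
    nucleus_classes: dict[int, str]
    nucleus_centroids: dict[int, tuple[float, float]]
    true_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class LabeledPixels:
    """A pixel-label training sample: ``coords[i]`` has tissue ``labels[i]``
    (1 = nest, 0 = stroma)."""

    coords: np.ndarray  # (N, 2) row, col
    labels: np.ndarray  # (N,)


def _ellipse_axes(area: float, ecc: float) -> tuple[float, float]:
    # pi*a*b = area with b = a*sqrt(1-ecc^2)
    ratio = np.sqrt(max(1.0 - ecc**2, 1e-4))
    a = np.sqrt(area / (np.pi * ratio))
    return a, a * ratio


def _place_nests(scenario: ImageScenario, rng: np.random.Generator) -> np.ndarray:
    h, w = scenario.height, scenario.width
    nest_mask = np.zeros((h, w), dtype=np.int32)
    r_typ = np.sqrt(scenario.nest_area_mean / np.pi)
    centers: list[tuple[float, float]] = []
    for nest_id in range(1, scenario.n_nests + 1):
        for _ in range(100):
            cy = rng.uniform(0.12 * h, 0.88 * h)
            cx = rng.uniform(0.12 * w, 0.88 * w)
            if all(np.hypot(cy - y, cx - x) > 2.1 * r_typ for y, x in centers):
                break
        centers.append((cy, cx))
        target = max(400.0, rng.normal(scenario.nest_area_mean, np.sqrt(scenario.nest_area_var)))
        k = int(rng.integers(1, 5))
        # overlapping lobes; 1.25 compensates the union losing area to overlap
        lobe_area = 1.25 * target / k
        for _ in range(k):
            ecc = rng.uniform(0.3, 0.75)
            a, b = _ellipse_axes(lobe_area, ecc)
            jy = cy + rng.normal(0, 0.45 * r_typ)
            jx = cx + rng.normal(0, 0.45 * r_typ)
            rot = rng.uniform(0, np.pi)
            rr, cc = draw.ellipse(jy, jx, a, b, shape=(h, w), rotation=rot)
            nest_mask[rr, cc] = nest_id
    return nest_mask


def _sample_nucleus_shape(
    scenario: ImageScenario, cls: str, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """Return (area, ecc, a, b) for one nucleus of class ``cls``."""
    sd = np.sqrt(scenario.nucleus_area_var)
    area = float(np.clip(rng.normal(scenario.nucleus_area_mean, sd), 40.0, None))
    if cls == STROMAL_ROUND:
        ecc = rng.uniform(0.0, 0.4)
        area *= 0.7  # immune-cell nuclei are smaller
    elif cls == STROMAL_NONROUND:
        ecc = rng.uniform(scenario.nonround_eccentricity_min, 0.97)
    else:
        ecc = rng.uniform(0.4, 0.85)
    a, b = _ellipse_axes(area, ecc)
    return area, ecc, a, b


def generate_he_image(scenario: ImageScenario) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic HE field and its ground truth.

    Returns
    -------
    image : (H, W, 3) uint8 RGB
    truth : GroundTruth with nest/nuclei label masks, per-nucleus class map
        and per-class true counts.

    Raises
    ------
    ValueError
        If requested densities would force more than 80% nucleus overlap
        ("infeasible density").
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    h, w = scenario.height, scenario.width

    nest_mask = _place_nests(scenario, rng) if scenario.n_nests > 0 else np.zeros(
        (h, w), dtype=np.int32
    )
    nest_area = int((nest_mask > 0).sum())
    stroma_area = h * w - nest_area

    n_epi = int(round(scenario.nuclei_density_in_nest * nest_area))
    n_round = int(round(scenario.stromal_round_density * stroma_area))
    n_nonround = int(round(scenario.stromal_nonround_density * stroma_area))

    mean_area = scenario.nucleus_area_mean
    if nest_area and n_epi * mean_area > 0.8 * nest_area:
        raise ValueError("infeasible density: epithelial nuclei would overlap > 80%")
    if stroma_area and (n_round * 0.7 + n_nonround) * mean_area > 0.8 * stroma_area:
        raise ValueError("infeasible density: stromal nuclei would overlap > 80%")

    nuclei_mask = np.zeros((h, w), dtype=np.int32)
    hema_od = np.full((h, w), 0.02)
    classes: dict[int, str] = {}
    centroids: dict[int, tuple[float, float]] = {}

    nest_coords = np.argwhere(nest_mask > 0)
    stroma_coords = np.argwhere(nest_mask == 0)

    plan = [(EPITHELIAL, n_epi, nest_coords)] + [
        (STROMAL_ROUND, n_round, stroma_coords),
        (STROMAL_NONROUND, n_nonround, stroma_coords),
    ]
    nucleus_id = 0
    placed: list[tuple[float, float, float]] = []  # (cy, cx, effective radius)
    for cls, n_req, coords in plan:
        if n_req > 0 and len(coords) == 0:
            raise ValueError("infeasible density: no pixels available for class " + cls)
        for _ in range(n_req):
            nucleus_id += 1
            area, ecc, a, b = _sample_nucleus_shape(scenario, cls, rng)
            r_eff = np.sqrt(area / np.pi)
            rot = rng.uniform(0, np.pi)
            for _attempt in range(80):
                cy, cx = coords[rng.integers(len(coords))]
                rr, cc = draw.ellipse(cy, cx, a, b, shape=(h, w), rotation=rot)
                if len(rr) == 0:
                    continue
                # keep nuclei separated; the spacing demand relaxes slowly
                # so extreme densities still place every requested nucleus
                factor = max(0.5, 1.1 * 0.99**_attempt)
                if all(
                    np.hypot(cy - py, cx - px) >= factor * (r_eff + pr)
                    for py, px, pr in placed
                ):
                    break
            nuclei_mask[rr, cc] = nucleus_id
            placed.append((float(cy), float(cx), r_eff))
            classes[nucleus_id] = cls
            centroids[nucleus_id] = (float(cy), float(cx))
            # elliptical Gaussian OD blob peaking at the centroid,
            # evaluated only on the blob's bounding window
            peak = rng.uniform(0.55, 0.75)
            r_ext = int(np.ceil(1.5 * a)) + 1
            y0, y1 = max(0, int(cy) - r_ext), min(h, int(cy) + r_ext + 1)
            x0, x1 = max(0, int(cx) - r_ext), min(w, int(cx) + r_ext + 1)
            dy = np.arange(y0, y1)[:, None] - cy
            dx = np.arange(x0, x1)[None, :] - cx
            u = dy * np.cos(rot) + dx * np.sin(rot)
            v = -dy * np.sin(rot) + dx * np.cos(rot)
            d2 = (u / a) ** 2 + (v / b) ** 2
            # flat-topped (super-Gaussian) chromatin profile: near-constant
            # OD inside the ellipse, fast falloff just outside so adjacent
            # nuclei keep a deep saddle between their peaks
            blob = np.where(d2 <= 1.8, peak * np.exp(-0.9 * d2**3), 0.0)
            hema_od[y0:y1, x0:x1] += blob

    truth = GroundTruth(
        nest_mask=nest_mask,
        nuclei_mask=nuclei_mask,
        nucleus_classes=classes,
        nucleus_centroids=centroids,
        true_counts={
            EPITHELIAL: n_epi,
            STROMAL_ROUND: n_round,
            STROMAL_NONROUND: n_nonround,
        },
    )

    eosin_od = np.where(nest_mask > 0, 0.25, 0.38)
    eosin_od = eosin_od + gaussian_filter(rng.normal(0.0, 0.03, (h, w)), 8)
    eosin_od = np.clip(eosin_od, 0.0, None)

    conc = np.stack([hema_od, eosin_od, np.zeros((h, w))], axis=-1)
    od = conc.reshape(-1, 3) @ HE_STAIN_MATRIX
    intensity = 255.0 * 10.0 ** (-od.reshape(h, w, 3))
    if scenario.illumination_gradient:
        g = scenario.illumination_gradient
        ramp = np.linspace(1 - g / 2, 1 + g / 2, w)[None, :, None]
        intensity = intensity * ramp
    if scenario.stain_noise_sd > 0:
        intensity = intensity + rng.normal(0.0, scenario.stain_noise_sd, intensity.shape)
    image = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return image, truth


def generate_labeled_pixels(
    image: np.ndarray, truth: GroundTruth, n_per_class: int, seed: int
) -> LabeledPixels:
    """Sample ``n_per_class`` pixel coordinates per tissue class (nest and
    stroma) from the ground truth, without replacement."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    coords_list, labels_list = [], []
    for label, sel in ((1, truth.nest_mask > 0), (0, truth.nest_mask == 0)):
        pix = np.argwhere(sel)
        if len(pix) < n_per_class:
            raise ValueError(
                f"class {label} has only {len(pix)} pixels < {n_per_class}"
            )
        idx = rng.choice(len(pix), size=n_per_class, replace=False)
        coords_list.append(pix[idx])
        labels_list.append(np.full(n_per_class, label))
    return LabeledPixels(
        coords=np.concatenate(coords_list), labels=np.concatenate(labels_list)
    )


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortScenario:
    """Parameters for a synthetic survival cohort.

    ``betas`` maps feature names to log-hazard coefficients; features listed
    in ``binary_features`` are Bernoulli(0.5), all others standard normal.
    Event times are exponential with hazard
    ``baseline_hazard * exp(sum(beta * x))``; the defaults give roughly a
    two-thirds event fraction over an 8-year (96-month) follow-up window,
    typical of a node-mixed invasive ductal carcinoma cohort.
    """

    n_patients: int = 230
    images_per_patient: int = 5
    betas: dict[str, float] = field(default_factory=dict)
    binary_features: tuple[str, ...] = ()
    baseline_hazard: float = 0.012  # events / month
    censor_rate: float = 0.2
    follow_up_max: float = 96.0  # months
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0 <= self.censor_rate <= 1):
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.baseline_hazard < 0:
            raise ValueError("baseline_hazard must be >= 0")


@dataclass
class Cohort:
    """A synthetic cohort: one row per patient plus an image-slot table."""

    patients: pd.DataFrame  # patient_id, time, event, <features...>
    images: pd.DataFrame  # patient_id, image_id


def draw_survival_times(
    features: pd.DataFrame,
    betas: dict[str, float],
    baseline_hazard: float,
    censor_rate: float,
    follow_up_max: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw exponential event times with hazard ``baseline * exp(X beta)``.

    Censoring is the minimum of an exponential censor draw and
    ``follow_up_max``; the censor rate sets P(censored before event) under
    the null model, i.e. the censor hazard is
    ``baseline * censor_rate / (1 - censor_rate)``.
    """
    n = len(features)
    lp = np.zeros(n)
    for name, beta in betas.items():
        if name not in features.columns:
            raise KeyError(f"beta refers to unknown feature {name!r}")
        lp += beta * features[name].to_numpy(float)
    hazard = baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / np.maximum(hazard, 1e-12))
    if censor_rate >= 1.0:
        censor_time = np.zeros(n)
    elif censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    censor_time = np.minimum(censor_time, follow_up_max)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    # survival times are strictly positive months
    time = np.maximum(time, 1e-6)
    return time, event


def generate_cohort(scenario: CohortScenario) -> Cohort:
    """Generate a cohort with feature-dependent exponential hazards."""
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_patients
    feat = {}
    for name in scenario.betas:
        if name in scenario.binary_features:
            feat[name] = rng.integers(0, 2, size=n).astype(float)
        else:
            feat[name] = rng.standard_normal(n)
    features = pd.DataFrame(feat, index=range(n))
    time, event = draw_survival_times(
        features,
        scenario.betas,
        scenario.baseline_hazard,
        scenario.censor_rate,
        scenario.follow_up_max,
        rng,
    )
    patients = pd.DataFrame({"patient_id": np.arange(n), "time": time, "event": event})
    patients = pd.concat([patients, features], axis=1)
    images = pd.DataFrame(
        {
            "patient_id": np.repeat(np.arange(n), scenario.images_per_patient),
            "image_id": [
                f"p{p:04d}_img{i}"
                for p in range(n)
                for i in range(scenario.images_per_patient)
            ],
        }
    )
    return Cohort(patients=patients, images=images)
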