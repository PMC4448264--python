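"""Composite prognostic features: printed linear formulas and PCA fits.

Two composite features summarize the tumor-nest architecture block and the
epithelial-nuclei morphometry block as linear combinations of z-standardized
catalog parameters:

    TNs feature          = 0.260 * TNs number + 0.107 * TNs perimeter sum
                           - 0.281 * TNs area average
                           - 0.272 * TNs area variance
                           - 0.268 * TNs area/perimeter ratio
    TNs cell nuclei feat = 0.048 * eccentricity maximum
                           + 0.482 * nuclei area average
                           + 0.478 * nuclei area variance
                           + 0.246 * nuclei area / TNs area ratio

Fresh coefficients for the same blocks can be fit on a cohort as first
principal-component loadings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: The two parameter blocks behind the composites.
TNS_BLOCK = (
    "tns_number",
    "tns_perimeter_sum",
    "tns_area_average",
    "tns_area_variance",
    "tns_area_perimeter_ratio",
)
NUCLEI_BLOCK = (
    "tns_cell_nuclei_eccentricity_maximum",
    "tns_cell_nuclei_area_average",
    "tns_cell_nuclei_area_variance",
    "tns_cell_nuclei_area_tns_area_ratio",
)


@dataclass
class CompositeSpec:
    """A named linear combination of catalog parameters."""

    name: str
    terms: list[tuple[str, float]]
    standardize_inputs: bool = True

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("composite needs at least one term")

    def coefficients(self) -> dict[str, float]:
        return dict(self.terms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.name, p, c) for p, c in self.terms],
            columns=["composite", "parameter", "coefficient"],
        )


TNS_FEATURE = CompositeSpec(
    name="tns_feature",
    terms=[
        ("tns_number", 0.260),
        ("tns_perimeter_sum", 0.107),
        ("tns_area_average", -0.281),
        ("tns_area_variance", -0.272),
        ("tns_area_perimeter_ratio", -0.268),
    ],
)

TNS_NUCLEI_FEATURE = CompositeSpec(
    name="tns_cell_nuclei_feature",
    terms=[
        ("tns_cell_nuclei_eccentricity_maximum", 0.048),
        ("tns_cell_nuclei_area_average", 0.482),
        ("tns_cell_nuclei_area_variance", 0.478),
        ("tns_cell_nuclei_area_tns_area_ratio", 0.246),
    ],
)

PRINTED_COMPOSITES = (TNS_FEATURE, TNS_NUCLEI_FEATURE)


def evaluate_composite(
    spec: CompositeSpec,
    features: pd.Series | dict,
    means: pd.Series | dict | None = None,
    sds: pd.Series | dict | None = None,
) -> float:
    """Evaluate one composite on a feature vector.

    With ``standardize_inputs`` (the default), each parameter is z-scored
    with the cohort ``means``/``sds`` before applying the coefficients; when
    none are supplied the values are taken as already standardized.  A
    missing (NaN) parameter makes the composite missing.
    """
    total = 0.0
    for param, coeff in spec.terms:
        try:
            x = float(features[param])
        except KeyError as exc:
            raise KeyError(f"composite {spec.name}: parameter {param!r} absent") from exc
        if spec.standardize_inputs and means is not None:
            sd = float(sds[param])
            if sd <= 0:
                raise ValueError(f"zero sd for {param!r}; cannot standardize")
            x = (x - float(means[param])) / sd
        if np.isnan(x):
            return float("nan")
        total += coeff * x
    return total


def evaluate_composites_frame(
    frame: pd.DataFrame, specs=PRINTED_COMPOSITES
) -> pd.DataFrame:
    """Evaluate composites for every row of a cohort feature table,
    standardizing each parameter with the table's own mean/sd.

    A parameter constant across the cohort carries no information; its
    standardized value is taken as 0 (with a warning) instead of failing."""
    import warnings

    means, sds = frame.mean(), frame.std(ddof=0)
    constant = sds[sds <= 0].index.tolist()
    if constant:
        warnings.warn(f"constant parameters contribute 0 to composites: {constant}")
        sds = sds.replace(0, np.inf)
    out = {}
    for spec in specs:
        out[spec.name] = frame.apply(
            lambda row: evaluate_composite(spec, row, means, sds), axis=1
        )
    return pd.DataFrame(out, index=frame.index)


def fit_pca_composites(
    cohort_features: pd.DataFrame, blocks: dict[str, list[str]]
) -> list[CompositeSpec]:
    """First-PC loadings per block as fresh composite coefficients.

    Parameters are z-standardized; constant parameters are dropped with a
    warning; the loading sign is fixed so the largest-magnitude loading is
    positive.  Loadings have unit Euclidean norm.
    """
    import warnings

    if len(cohort_features) < 3:
        raise ValueError("need at least 3 patients to fit composites")
    specs = []
    for name, params in blocks.items():
        sub = cohort_features[list(params)]
        sds = sub.std(ddof=0)
        constant = [p for p in params if sds[p] <= 0]
        if constant:
            warnings.warn(f"block {name}: dropping constant parameters {constant}")
        kept = [p for p in params if p not in constant]
        if not kept:
            raise ValueError(f"block {name}: all parameters constant")
        z = (sub[kept] - sub[kept].mean()) / sds[kept]
        pca = PCA(n_components=1, svd_solver="full").fit(z.to_numpy())
        load = pca.components_[0]
        if load[np.argmax(np.abs(load))] < 0:
            load = -load
        specs.append(CompositeSpec(name=name, terms=list(zip(kept, load.tolist()))))
    return specs
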