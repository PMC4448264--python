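"""Nucleus classification into epithelial / stromal-round / stromal-non-round.

A nucleus whose centroid falls inside a tumor nest is epithelial; stromal
nuclei are split by eccentricity into round (infiltrating-immune-cell-like)
and non-round (fibroblast / vessel-like) classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nuclei import NucleusObject
from .synthetic import EPITHELIAL, STROMAL_NONROUND, STROMAL_ROUND


@dataclass
class ClassifiedNuclei:
    """Nuclei partitioned into the three cell classes."""

    nuclei: list[NucleusObject]
    counts: dict[str, int] = field(default_factory=dict)

    def of_class(self, cls: str) -> list[NucleusObject]:
        return [n for n in self.nuclei if n.label_class == cls]

    def centroids(self, cls: str) -> np.ndarray:
        pts = [n.centroid for n in self.nuclei if n.label_class == cls]
        return np.asarray(pts, dtype=float).reshape(-1, 2)


def classify_nuclei(
    nuclei: list[NucleusObject],
    tissue_mask: np.ndarray,
    ecc_round_max: float = 0.8,
) -> ClassifiedNuclei:
    """Assign every nucleus to one of the three classes.

    Membership in a nest is decided by the centroid pixel of the nucleus
    (rounded to the nearest pixel), matching the pseudo-color rendering.
    """
    if not (0 < ecc_round_max < 1):
        raise ValueError("ecc_round_max must lie in (0, 1)")
    mask = np.asarray(tissue_mask)
    h, w = mask.shape
    counts = {EPITHELIAL: 0, STROMAL_ROUND: 0, STROMAL_NONROUND: 0}
    for n in nuclei:
        r, c = int(round(n.centroid[0])), int(round(n.centroid[1]))
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"nucleus {n.id} centroid {n.centroid} outside image")
        if mask[r, c]:
            n.label_class = EPITHELIAL
        elif n.eccentricity < ecc_round_max:
            n.label_class = STROMAL_ROUND
        else:
            n.label_class = STROMAL_NONROUND
        counts[n.label_class] += 1
    return ClassifiedNuclei(nuclei=list(nuclei), counts=counts)
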