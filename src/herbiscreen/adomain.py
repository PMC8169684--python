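"""Applicability-domain (AD) gating of classifier predictions.

A prediction is considered reliable only inside the model's applicability
domain, defined by two conditions that must hold simultaneously:

* similarity to the training set — minimum Jaccard distance on retained
  MACCS keys strictly below 0.4 (i.e. Tanimoto similarity above 0.6 to at
  least one training compound) for the structural AD, or minimum Euclidean
  distance strictly below 2.0 in the training-scaled nine-descriptor space
  for the physicochemical AD;
* confidence — the maximum class probability strictly above 0.6.

Out-of-domain compounds keep their predicted label but are flagged
unclassified in summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .modeling import ClassifierBundle
from .simclust import min_euclidean_distance, min_jaccard_distance


@dataclass(frozen=True)
class ADThresholds:
    max_distance: float
    min_class_prob: float = 0.6

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValidationError("distance threshold must be positive")
        if not 0 < self.min_class_prob < 1:
            raise ValidationError("probability threshold must lie in (0, 1)")


@dataclass(frozen=True)
class ADConfig:
    """Thresholds for the structural and physicochemical domains."""

    structural: ADThresholds = field(
        default_factory=lambda: ADThresholds(max_distance=0.4)
    )
    physchem: ADThresholds = field(
        default_factory=lambda: ADThresholds(max_distance=2.0)
    )


@dataclass(frozen=True)
class ADVerdict:
    """Outcome of one AD check; ``in_domain`` iff no condition failed."""

    in_domain: bool
    distance: float
    max_prob: float
    failed_conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.in_domain != (len(self.failed_conditions) == 0):
            raise ValidationError("in_domain must mirror failed_conditions")


def _check(distance: float, max_prob: float, thresholds: ADThresholds) -> ADVerdict:
    if not 0 <= max_prob <= 1:
        raise ValidationError("max_prob must lie in [0, 1]")
    if distance < 0:
        raise ValidationError("distance must be non-negative")
    failed = []
    if not distance < thresholds.max_distance:
        failed.append("similarity")
    if not max_prob > thresholds.min_class_prob:
        failed.append("probability")
    return ADVerdict(
        in_domain=not failed, distance=float(distance),
        max_prob=float(max_prob), failed_conditions=tuple(failed),
    )


def structural_ad_check(
    min_jaccard: float, max_prob: float, cfg: ADConfig = ADConfig()
) -> ADVerdict:
    """In-domain iff min Jaccard distance < 0.4 and class probability > 0.6.

    Both inequalities are strict, so boundary values fall outside the domain.
    """
    if min_jaccard > 1:
        raise ValidationError("Jaccard distance must lie in [0, 1]")
    return _check(min_jaccard, max_prob, cfg.structural)


def physchem_ad_check(
    min_euclid: float, max_prob: float, cfg: ADConfig = ADConfig()
) -> ADVerdict:
    """In-domain iff min Euclidean distance < 2.0 and class probability > 0.6.

    The distance must be computed in the training-scaled descriptor space.
    """
    return _check(min_euclid, max_prob, cfg.physchem)


class StructuralAD:
    """Structural applicability domain bound to a fingerprint model bundle."""

    def __init__(self, bundle: ClassifierBundle, cfg: ADConfig = ADConfig()):
        if bundle.retained_keys is None:
            raise ValidationError(
                "structural AD requires a fingerprint-trained bundle"
            )
        self.bundle = bundle
        self.cfg = cfg

    def verdicts(self, query_bits: np.ndarray, max_probs: np.ndarray) -> list[ADVerdict]:
        query_bits = np.atleast_2d(query_bits)
        if query_bits.shape[1] != self.bundle.training_features.shape[1]:
            raise ValidationError("retained-key columns do not match the bundle")
        return [
            structural_ad_check(
                min_jaccard_distance(row, self.bundle.training_features),
                p, self.cfg,
            )
            for row, p in zip(query_bits, np.atleast_1d(max_probs))
        ]


class PhyschemAD:
    """Physicochemical applicability domain bound to a descriptor model bundle."""

    def __init__(self, bundle: ClassifierBundle, cfg: ADConfig = ADConfig()):
        if bundle.scaling_stats is None:
            raise ValidationError(
                "physicochemical AD requires a descriptor-trained bundle "
                "with scaling statistics"
            )
        self.bundle = bundle
        self.cfg = cfg

    def verdicts(self, scaled_query: np.ndarray, max_probs: np.ndarray) -> list[ADVerdict]:
        scaled_query = np.atleast_2d(np.asarray(scaled_query, dtype=float))
        if scaled_query.shape[1] != self.bundle.training_features.shape[1]:
            raise ValidationError("descriptor columns do not match the bundle")
        return [
            physchem_ad_check(
                min_euclidean_distance(row, self.bundle.training_features),
                p, self.cfg,
            )
            for row, p in zip(scaled_query, np.atleast_1d(max_probs))
        ]
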