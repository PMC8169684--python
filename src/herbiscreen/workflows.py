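"""End-to-end training workflows composing the lower-level modules.

These helpers wire the standard study design together: stratified splitting,
feature building (frequency-selected MACCS keys or the scaled nine-descriptor
set), grid-searched cross-validated training, and bundle assembly for
applicability-domain gating. They are what the CLI and the screening cascade
consume.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .chem_io import CompoundSet
from .descriptors import (
    NINE_DESCRIPTORS,
    fingerprint_matrix,
    physchem_table,
    scale_columns,
    select_frequent_keys,
)
from .errors import ValidationError
from .modeling import ClassifierBundle, SplitSpec, stratified_split, tune_and_train


def build_fingerprint_features(
    compounds: CompoundSet, min_count: int = 5
) -> tuple[pd.DataFrame, list[int]]:
    """Frequency-selected MACCS key matrix for a compound set (rows = ids)."""
    fp = fingerprint_matrix(compounds.ids, compounds.smiles())
    retained = select_frequent_keys(fp, min_count)
    frame = pd.DataFrame(
        fp.bits[:, [k - 1 for k in retained]],
        index=compounds.ids,
        columns=[f"MACCS_{k}" for k in retained],
    )
    return frame, retained


def train_moa_bundle(
    compounds: CompoundSet,
    label_field: str = "moa_label",
    split: SplitSpec = SplitSpec(),
    min_count: int = 5,
    algorithm: str = "rf",
    cv: Mapping[str, int] | None = None,
    n_trees: int = 500,
    grid: list[dict] | None = None,
) -> tuple[ClassifierBundle, list[str], list[str]]:
    """Train a mode-of-action classifier on retained MACCS keys.

    Key selection runs on the training compounds only (leak-free), and the
    bundle keeps the training bit matrix for structural-AD distances.
    Returns (bundle, test ids, excluded ids).
    """
    train_ids, test_ids, excluded = stratified_split(compounds, label_field, split)
    if not train_ids:
        raise ValidationError("no trainable classes after exclusion")
    train_set = compounds.subset(train_ids)
    features, retained = build_fingerprint_features(train_set, min_count)
    labels = [l for l in train_set.labels(label_field)]
    bundle = tune_and_train(
        features.to_numpy(), labels,
        algorithm=algorithm, cv=cv, seed=split.seed, grid=grid,
        label_field=label_field,
        feature_names=list(features.columns),
        training_ids=train_set.ids,
        retained_keys=retained,
        n_trees=n_trees,
    )
    return bundle, test_ids, excluded


def moa_features_for(
    compounds: CompoundSet, bundle: ClassifierBundle
) -> pd.DataFrame:
    """Fingerprint features for new compounds, restricted to bundle keys."""
    if bundle.retained_keys is None:
        raise ValidationError("bundle was not trained on fingerprints")
    fp = fingerprint_matrix(compounds.ids, compounds.smiles())
    return pd.DataFrame(
        fp.bits[:, [k - 1 for k in bundle.retained_keys]],
        index=compounds.ids, columns=bundle.feature_names,
    )


def train_selectivity_bundle(
    compounds: CompoundSet,
    label_field: str = "selectivity_label",
    split: SplitSpec = SplitSpec(),
    descriptors: Sequence[str] = NINE_DESCRIPTORS,
    algorithm: str = "rf",
    cv: Mapping[str, int] | None = None,
    n_trees: int = 500,
    grid: list[dict] | None = None,
    overrides: pd.DataFrame | None = None,
) -> tuple[ClassifierBundle, list[str], list[str]]:
    """Train a weed-selectivity classifier on scaled descriptors.

    Scaling statistics are learned on the training rows only and stored in
    the bundle, together with the scaled training matrix, for
    physicochemical-AD distances. Returns (bundle, test ids, excluded ids).
    """
    train_ids, test_ids, excluded = stratified_split(compounds, label_field, split)
    if not train_ids:
        raise ValidationError("no trainable classes after exclusion")
    train_set = compounds.subset(train_ids)
    table = physchem_table(train_set.ids, train_set.smiles(), overrides=overrides)
    table = table[list(descriptors)]
    scaled, stats = scale_columns(table)
    labels = [l for l in train_set.labels(label_field)]
    bundle = tune_and_train(
        scaled.to_numpy(), labels,
        algorithm=algorithm, cv=cv, seed=split.seed, grid=grid,
        label_field=label_field,
        feature_names=list(table.columns),
        training_ids=train_set.ids,
        scaling_stats=stats,
        n_trees=n_trees,
    )
    return bundle, test_ids, excluded


def selectivity_features_for(
    compounds: CompoundSet, bundle: ClassifierBundle,
    overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Scaled descriptor features for new compounds, via bundle statistics."""
    if bundle.scaling_stats is None:
        raise ValidationError("bundle carries no scaling statistics")
    table = physchem_table(compounds.ids, compounds.smiles(), overrides=overrides)
    return bundle.scaling_stats.apply(table)
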