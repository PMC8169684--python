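"""Herbicide-likeness rules and the stepwise virtual screening cascade.

The likeness filter scores six descriptor families against empirical bounds
observed for marketed synthetic herbicides:

====================  =======================================
HBD (OH/NH)           <= 2
HBA (O/N)             <= 6 (strict) / <= 7 (lenient)
clogP                 0.5 < clogP <= 3.5 (strict) / <= 4.5 (lenient)
TPSA                  20 A^2 < TPSA <= 120 A^2
Relative PSA          0.1 < RelPSA <= 0.5
Net charge            <= 0
====================  =======================================

A compound is herbicide-like when it satisfies at least ``min_criteria``
(default 4) of the six. The cascade then predicts weed selectivity (gated by
the physicochemical applicability domain) and mode of action (gated by the
structural applicability domain), producing one report row per compound.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .adomain import ADConfig, PhyschemAD, StructuralAD
from .chem_io import CompoundSet
from .descriptors import (
    DescriptorVector,
    NINE_DESCRIPTORS,
    fingerprint_matrix,
    physchem_table,
)
from .errors import ValidationError
from .modeling import ClassifierBundle

LIKENESS_DESCRIPTORS = ("HBD", "HBA", "clogP", "TPSA", "RelPSA", "net_charge")

STAGE_REJECTED = "rejected_likeness"
STAGE_SELECTIVITY = "selectivity_predicted"
STAGE_MOA = "moa_predicted"


@dataclass(frozen=True)
class LikenessRuleSet:
    """Bounds of the herbicide-like chemical space, with a strict/lenient switch.

    The lenient variant relaxes only the HBA ceiling (7 instead of 6) and the
    clogP upper bound (4.5 instead of 3.5); all other families are identical.
    Lower bounds are strict, upper bounds inclusive.
    """

    hbd_max: int = 2
    hba_max_strict: int = 6
    hba_max_lenient: int = 7
    clogp_lower: float = 0.5
    clogp_upper_strict: float = 3.5
    clogp_upper_lenient: float = 4.5
    tpsa_lower: float = 20.0
    tpsa_upper: float = 120.0
    relpsa_lower: float = 0.1
    relpsa_upper: float = 0.5
    net_charge_max: int = 0
    variant: str = "lenient"
    min_criteria: int = 4

    def __post_init__(self) -> None:
        if self.variant not in ("strict", "lenient"):
            raise ValidationError("variant must be 'strict' or 'lenient'")
        if not 0 <= self.min_criteria <= 6:
            raise ValidationError("min_criteria must lie in 0..6")

    @property
    def hba_max(self) -> int:
        return self.hba_max_strict if self.variant == "strict" else self.hba_max_lenient

    @property
    def clogp_upper(self) -> float:
        return (self.clogp_upper_strict if self.variant == "strict"
                else self.clogp_upper_lenient)


def likeness_evaluate(
    descriptors: DescriptorVector | Mapping[str, float],
    rules: LikenessRuleSet = LikenessRuleSet(),
) -> tuple[dict[str, bool], int]:
    """Evaluate the six likeness families on raw-unit descriptor values.

    Returns the per-family pass flags (in fixed order HBD, HBA, clogP, TPSA,
    RelPSA, net_charge) and the number satisfied.
    """
    if isinstance(descriptors, DescriptorVector):
        if descriptors.scaled:
            raise ValidationError("likeness rules need raw-unit descriptors")
        values: Mapping[str, float] = descriptors.as_dict()
    else:
        values = descriptors
    missing = [name for name in LIKENESS_DESCRIPTORS
               if name not in values or pd.isna(values[name])]
    if missing:
        raise ValidationError(f"missing descriptor(s) for likeness rules: {missing}")
    flags = {
        "HBD": values["HBD"] <= rules.hbd_max,
        "HBA": values["HBA"] <= rules.hba_max,
        "clogP": rules.clogp_lower < values["clogP"] <= rules.clogp_upper,
        "TPSA": rules.tpsa_lower < values["TPSA"] <= rules.tpsa_upper,
        "RelPSA": rules.relpsa_lower < values["RelPSA"] <= rules.relpsa_upper,
        "net_charge": values["net_charge"] <= rules.net_charge_max,
    }
    return flags, sum(flags.values())


class LikenessFilter:
    """Vectorised likeness evaluation over a descriptor table."""

    def __init__(self, rules: LikenessRuleSet = LikenessRuleSet()):
        self.rules = rules

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for _, row in table.iterrows():
            flags, count = likeness_evaluate(row.to_dict(), self.rules)
            rows.append({**{f"pass_{k}": v for k, v in flags.items()},
                         "likeness_count": count,
                         "herbicide_like": count >= self.rules.min_criteria})
        return pd.DataFrame(rows, index=table.index)


def _validate_bundles(
    selectivity_bundle: ClassifierBundle, moa_bundle: ClassifierBundle
) -> None:
    if moa_bundle.retained_keys is None:
        raise ValidationError("MoA bundle must be fingerprint-trained "
                              "(retained_keys missing)")
    if selectivity_bundle.scaling_stats is None:
        raise ValidationError("selectivity bundle must carry scaling statistics")
    if len(moa_bundle.retained_keys) != moa_bundle.training_features.shape[1]:
        raise ValidationError("MoA bundle retained keys do not match its "
                              "training matrix")
    expected = list(selectivity_bundle.scaling_stats.mean.index)
    if expected != list(selectivity_bundle.feature_names):
        raise ValidationError("selectivity bundle scaling statistics do not "
                              "match its feature names")


def screen_cascade(
    compounds: CompoundSet,
    selectivity_bundle: ClassifierBundle,
    moa_bundle: ClassifierBundle,
    rules: LikenessRuleSet = LikenessRuleSet(),
    ad_cfg: ADConfig = ADConfig(),
    audit: bool = False,
    descriptor_overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the stepwise screen: likeness filter, selectivity, mode of action.

    Stage 1 keeps compounds satisfying ``rules.min_criteria`` of the six
    likeness families; stage 2 predicts weed selectivity with
    physicochemical-AD gating; stage 3 predicts mode of action with
    structural-AD gating. Compounds stop at the first failed gate unless
    ``audit`` is true, in which case every quantity is computed for every
    compound (gates still decide ``stage_reached``). One report row per
    compound, in input order.
    """
    _validate_bundles(selectivity_bundle, moa_bundle)
    ids = compounds.ids
    smiles = compounds.smiles(clean=True)

    table = physchem_table(ids, smiles, overrides=descriptor_overrides)
    likeness = LikenessFilter(rules).transform(table)

    fp = fingerprint_matrix(ids, smiles)
    fp_bits = fp.bits[:, [k - 1 for k in moa_bundle.retained_keys]]
    scaled = selectivity_bundle.scaling_stats.apply(table).to_numpy()

    phys_ad = PhyschemAD(selectivity_bundle, ad_cfg)
    struct_ad = StructuralAD(moa_bundle, ad_cfg)

    report = pd.DataFrame(index=ids)
    report["smiles_clean"] = smiles
    report = pd.concat([report, likeness.set_axis(ids)], axis=1)

    n = len(ids)
    sel_label = np.full(n, None, dtype=object)
    sel_prob = np.full(n, np.nan)
    sel_in_ad = np.full(n, None, dtype=object)
    sel_ad_failed = np.full(n, None, dtype=object)
    moa_label = np.full(n, None, dtype=object)
    moa_prob = np.full(n, np.nan)
    moa_in_ad = np.full(n, None, dtype=object)
    moa_ad_failed = np.full(n, None, dtype=object)
    stage = np.full(n, STAGE_REJECTED, dtype=object)

    like_mask = likeness["herbicide_like"].to_numpy()
    sel_rows = np.arange(n) if audit else np.nonzero(like_mask)[0]
    if sel_rows.size:
        _, max_p, labels = selectivity_bundle.predict_with_probabilities(
            scaled[sel_rows]
        )
        verdicts = phys_ad.verdicts(scaled[sel_rows], max_p)
        sel_label[sel_rows] = labels
        sel_prob[sel_rows] = max_p
        sel_in_ad[sel_rows] = [v.in_domain for v in verdicts]
        sel_ad_failed[sel_rows] = [";".join(v.failed_conditions) for v in verdicts]

    stage[like_mask] = STAGE_SELECTIVITY
    sel_pass = like_mask & np.array(
        [bool(v) for v in np.where(sel_in_ad == None, False, sel_in_ad)]  # noqa: E711
    )
    moa_rows = np.arange(n) if audit else np.nonzero(sel_pass)[0]
    if moa_rows.size:
        _, max_p, labels = moa_bundle.predict_with_probabilities(fp_bits[moa_rows])
        verdicts = struct_ad.verdicts(fp_bits[moa_rows], max_p)
        moa_label[moa_rows] = labels
        moa_prob[moa_rows] = max_p
        moa_in_ad[moa_rows] = [v.in_domain for v in verdicts]
        moa_ad_failed[moa_rows] = [";".join(v.failed_conditions) for v in verdicts]
    stage[sel_pass] = STAGE_MOA

    report["stage_reached"] = stage
    report["selectivity_prediction"] = sel_label
    report["selectivity_probability"] = sel_prob
    report["selectivity_in_ad"] = sel_in_ad
    report["selectivity_ad_failed"] = sel_ad_failed
    report["moa_prediction"] = moa_label
    report["moa_probability"] = moa_prob
    report["moa_in_ad"] = moa_in_ad
    report["moa_ad_failed"] = moa_ad_failed
    # out-of-domain predictions keep their label but are flagged unclassified
    report["unclassified"] = [
    not (s == STAGE_MOA and bool(m)) for s, m in zip(stage, moa_in_ad)
    ]
    report.index.name = "id"
    return report


class ScreeningCascade:
    """Object wrapper over :func:`screen_cascade` holding bundles and config."""

    def __init__(
        self,
        selectivity_bundle: ClassifierBundle,
        moa_bundle: ClassifierBundle,
        rules: LikenessRuleSet = LikenessRuleSet(),
        ad_cfg: ADConfig = ADConfig(),
    ):
        _validate_bundles(selectivity_bundle, moa_bundle)
        self.selectivity_bundle = selectivity_bundle
        self.moa_bundle = moa_bundle
        self.rules = rules
        self.ad_cfg = ad_cfg

    def screen(self, compounds: CompoundSet, audit: bool = False,
               descriptor_overrides: pd.DataFrame | None = None) -> pd.DataFrame:
        return screen_cascade(
            compounds, self.selectivity_bundle, self.moa_bundle,
            self.rules, self.ad_cfg, audit=audit,
            descriptor_overrides=descriptor_overrides,
        )
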