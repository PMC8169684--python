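"""Structural fingerprints and physicochemical descriptors.

Two feature families feed the classifiers and the likeness filter:

* 166-bit MACCS structural keys, reduced to the subset of keys present in
  more than ``min_count`` training compounds (strictly greater);
* whole-molecule physicochemical descriptors — H-bond donors/acceptors,
  clogP, TPSA, relative PSA, net charge, molecular weight, carbon and sp3
  atom counts, a topological shape index, log water solubility and the
  log aqueous diffusion coefficient (Hayduk–Laudie).

Descriptors (never fingerprints) are standardised as (x - mean) / sd with
statistics learned on the training set and reused on external compounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, MACCSkeys, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_io import mol_from_clean_smiles
from .errors import ConfigurationError, DomainError, ValidationError

#: descriptor set used by the weed-selectivity models
NINE_DESCRIPTORS: tuple[str, ...] = (
    "logDiff", "logSw", "ShapeIndex", "Cat", "sp3At", "TPSA", "HBA", "HBD", "clogP",
)

#: all descriptor names a profile carries
DESCRIPTOR_NAMES: tuple[str, ...] = NINE_DESCRIPTORS + (
    "logD74", "RelPSA", "net_charge", "MW",
)

# Substructure rules for the net-ionisation heuristic: basic nitrogens
# (protonated at pH 7) minus acidic oxygens (deprotonated at pH 7).
_BASIC_N_SMARTS = (
    # aliphatic amines: not amide/sulfonamide N, not aromatic, not N-N/N-O
    "[NX3;H2,H1,H0;!$(N~[!#6;!#1]);!$(NC=[O,S,N]);!$(N[a]);!$(N=*);+0]",
    "[NX2;$(N=C[NX3]);+0]",           # amidine / guanidine =N-
    "[N+;!$([N+][O-]);!$([N+]=O)]",   # already-protonated / quaternary N
)
_ACIDIC_O_SMARTS = (
    "[OX2H1;$(OC=O)]",                # carboxylic acid OH
    "[OX2H1;$(O[S](=O)=O)]",          # sulfonic acid OH
    "[OX2H1;$(O[P](=O))]",            # phosphonic/phosphoric acid OH
    "[OX2H1;$(O[NX3]C=O)]",           # acidic N-hydroxy imide
    "[O-;!$([O-][N+])]",              # residual anionic O
)
_BASIC_N = [Chem.MolFromSmarts(s) for s in _BASIC_N_SMARTS]
_ACIDIC_O = [Chem.MolFromSmarts(s) for s in _ACIDIC_O_SMARTS]

# LeBas additive atomic volumes (cm^3/mol) for the molar-volume estimate
# feeding the Hayduk-Laudie diffusion formula.
_LEBAS_VOLUME = {
    "C": 14.8, "H": 3.7, "O": 7.4, "N": 15.6, "S": 25.6, "P": 27.0,
    "F": 8.7, "Cl": 24.6, "Br": 27.0, "I": 37.0,
}
_LEBAS_RING_6 = -15.0
_LEBAS_RING_5 = -11.5

_WATER_VISCOSITY_25C = 0.8904  # centipoise

# Additive approximate van-der-Waals surface contributions (A^2) per bonded
# atom, on the same scale as TPSA fragment contributions; the RelPSA
# denominator. Roughly 4*pi*r_vdw^2 discounted for bonding overlap.
_ATOM_SURFACE = {
    "H": 7.0, "C": 10.0, "N": 9.0, "O": 9.0, "F": 9.0,
    "Cl": 16.0, "Br": 19.0, "I": 23.0, "S": 16.0, "P": 16.0,
}


@dataclass
class FingerprintMatrix:
    """MACCS key matrix: compounds x 166 binary keys, with a retained subset."""

    ids: list[str]
    bits: np.ndarray                      # (n, 166) uint8, key k in column k-1
    retained_keys: list[int] = field(default_factory=list)  # 1-based key numbers

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[1] != 166:
            raise ValidationError("fingerprint matrix must be n x 166")
        if not set(np.unique(self.bits)) <= {0, 1}:
            raise ValidationError("fingerprint entries must be binary")
        if self.retained_keys != sorted(set(self.retained_keys)):
            raise ValidationError("retained_keys must be sorted and unique")

    @property
    def retained_bits(self) -> np.ndarray:
        """Bit matrix restricted to the retained keys (all keys if none set)."""
        if not self.retained_keys:
            return self.bits
        cols = [k - 1 for k in self.retained_keys]
        return self.bits[:, cols]


@dataclass
class ScalingStats:
    """Per-descriptor mean and sample standard deviation from a reference set."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        bad = self.sd.index[self.sd <= 0].tolist()
        if bad:
            raise ValidationError(f"non-positive sd for columns {bad}")

    def apply(self, frame: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.mean.index if c not in frame.columns]
        if missing:
            raise ValidationError(f"missing descriptor columns {missing}")
        cols = list(self.mean.index)
        return (frame[cols] - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "sd": self.sd.to_dict()}

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScalingStats":
        return cls(mean=pd.Series(data["mean"]), sd=pd.Series(data["sd"]))


@dataclass
class DescriptorVector:
    """Named physicochemical descriptors for one compound.

    ``external`` records which values were supplied as overrides rather than
    computed; ``scaled`` flags whether values are in raw units or standardised.
    """

    HBD: int
    HBA: int
    clogP: float
    TPSA: float
    RelPSA: float
    net_charge: int
    MW: float
    Cat: int
    sp3At: int
    ShapeIndex: float
    logSw: float
    logDiff: float
    logD74: float | None = None
    scaled: bool = False
    external: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.scaled:
            if min(self.HBD, self.HBA, self.Cat, self.sp3At) < 0:
                raise ValidationError("atom counts must be non-negative")
            if self.TPSA < 0 or not (0.0 <= self.RelPSA <= 1.0) or self.MW <= 0:
                raise ValidationError("descriptor out of physical range")

    def as_dict(self) -> dict[str, float]:
        out = {name: getattr(self, name) for name in DESCRIPTOR_NAMES}
        return {k: v for k, v in out.items() if v is not None}

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_dict())


def maccs_fingerprint(smiles: str) -> np.ndarray:
    """166-length binary MACCS key vector (key k at index k-1).

    RDKit's placeholder bit 0 is dropped so the vector indexes keys 1..166.
    """
    mol = mol_from_clean_smiles(smiles)
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(166, dtype=np.uint8)
    for bit in fp.GetOnBits():
        if bit >= 1:
            arr[bit - 1] = 1
    return arr


def fingerprint_matrix(ids: Sequence[str], smiles: Sequence[str]) -> FingerprintMatrix:
    if len(ids) != len(smiles):
        raise ValidationError("ids and smiles must have equal length")
    bits = np.vstack([maccs_fingerprint(s) for s in smiles]) if len(smiles) else np.zeros((0, 166), np.uint8)
    return FingerprintMatrix(ids=list(ids), bits=bits)


def select_frequent_keys(fp: FingerprintMatrix, min_count: int = 5) -> list[int]:
    """Keys present in strictly more than ``min_count`` compounds (1-based)."""
    if min_count < 0:
        raise ValidationError("min_count must be >= 0")
    if fp.bits.shape[0] == 0:
        raise ValidationError("empty fingerprint matrix")
    counts = fp.bits.sum(axis=0)
    return [int(k) + 1 for k in np.nonzero(counts > min_count)[0]]


def net_charge_estimate(smiles: str) -> int:
    """Net ionisation state at physiological pH: (#basic N) - (#acidic O)."""
    mol = mol_from_clean_smiles(smiles)
    basic = set()
    for patt in _BASIC_N:
        basic.update(m[0] for m in mol.GetSubstructMatches(patt))
    acidic = set()
    for patt in _ACIDIC_O:
        acidic.update(m[0] for m in mol.GetSubstructMatches(patt))
    return len(basic) - len(acidic)


def lebas_molar_volume(smiles: str) -> float:
    """Additive LeBas molar volume estimate (cm^3/mol), with ring corrections."""
    mol = mol_from_clean_smiles(smiles)
    molh = Chem.AddHs(mol)
    volume = 0.0
    for atom in molh.GetAtoms():
        volume += _LEBAS_VOLUME.get(atom.GetSymbol(), 20.0)
    for ring in mol.GetRingInfo().AtomRings():
        volume += _LEBAS_RING_6 if len(ring) >= 6 else _LEBAS_RING_5
    return max(volume, 10.0)


def hayduk_laudie_log_diffusion(
    molar_volume: float, viscosity: float = _WATER_VISCOSITY_25C
) -> float:
    """log10 of the aqueous diffusion coefficient in 1e-5 cm^2/s units.

    D = 13.26e-5 / (viscosity^1.14 * molar_volume^0.589) with viscosity in
    centipoise and molar volume in cm^3/mol.
    """
    if molar_volume <= 0 or viscosity <= 0:
        raise DomainError("molar_volume and viscosity must be positive")
    diff = 13.26e-5 / (viscosity ** 1.14 * molar_volume ** 0.589)
    return math.log10(diff / 1e-5)


def esol_log_solubility(mol: Chem.Mol, clogp: float) -> float:
    """Additive estimate of log10 native water solubility (mol/L).

    ESOL-style linear model in clogP, molecular weight, rotatable bonds and
    aromatic proportion; an open approximation for the solubility descriptor.
    """
    mw = RDDescriptors.MolWt(mol)
    rb = rdMolDescriptors.CalcNumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = sum(a.GetIsAromatic() for a in mol.GetAtoms()) / heavy if heavy else 0.0
    return 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def approx_total_surface_area(mol: Chem.Mol) -> float:
    """Additive approximate total molecular surface area (A^2), H included."""
    molh = Chem.AddHs(mol)
    return sum(_ATOM_SURFACE.get(a.GetSymbol(), 13.0) for a in molh.GetAtoms())


def topological_shape_index(mol: Chem.Mol) -> float:
    """Graph diameter / heavy-atom count; spherical < 0.5 < linear."""
    n = mol.GetNumHeavyAtoms()
    if n <= 1:
        return 0.0
    dmat = Chem.GetDistanceMatrix(mol)
    return float(dmat.max()) / n


def physchem_profile(
    smiles: str, overrides: Mapping[str, float] | None = None
) -> DescriptorVector:
    """Compute the full descriptor profile for one cleaned structure.

    ``overrides`` may supply any descriptor by name (e.g. externally
    calculated logD74 or logSw); supplied values win over computed ones and
    are flagged in ``external``.
    """
    overrides = dict(overrides or {})
    unknown = [k for k in overrides if k not in DESCRIPTOR_NAMES]
    if unknown:
        raise ConfigurationError(f"unknown descriptor override(s) {unknown}")
    mol = mol_from_clean_smiles(smiles)

    hbd = rdMolDescriptors.CalcNumHBD(mol)
    hba = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))
    clogp = float(Crippen.MolLogP(mol))
    if "clogP" in overrides:
        clogp = float(overrides["clogP"])
    tpsa = float(rdMolDescriptors.CalcTPSA(mol))
    total_sa = approx_total_surface_area(mol)
    relpsa = min(tpsa / total_sa, 1.0) if total_sa > 0 else 0.0
    values = {
        "HBD": hbd,
        "HBA": hba,
        "clogP": clogp,
        "TPSA": tpsa,
        "RelPSA": relpsa,
        "net_charge": net_charge_estimate(smiles),
        "MW": float(RDDescriptors.MolWt(mol)),
        "Cat": sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6),
        "sp3At": sum(
            1 for a in mol.GetAtoms()
            if a.GetHybridization() == Chem.HybridizationType.SP3
        ),
        "ShapeIndex": topological_shape_index(mol),
        "logSw": esol_log_solubility(mol, clogp),
        "logDiff": hayduk_laudie_log_diffusion(lebas_molar_volume(smiles)),
        "logD74": None,
    }
    for name, value in overrides.items():
        values[name] = float(value) if name not in ("HBD", "HBA", "Cat", "sp3At", "net_charge") else int(value)
    return DescriptorVector(external=frozenset(overrides), **values)


def physchem_table(
    ids: Sequence[str],
    smiles: Sequence[str],
    overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Descriptor table (one row per compound, indexed by id).

    ``overrides`` is an optional per-compound frame (indexed by id) of
    externally supplied descriptor columns.
    """
    rows = []
    for cid, smi in zip(ids, smiles):
        ov: dict[str, float] = {}
        if overrides is not None and cid in overrides.index:
            ov = {
                k: v for k, v in overrides.loc[cid].items()
                if pd.notna(v) and k in DESCRIPTOR_NAMES
            }
        rows.append(physchem_profile(smi, ov).as_dict())
    return pd.DataFrame(rows, index=list(ids))


def scale_columns(
    matrix: pd.DataFrame, ref: ScalingStats | None = None
) -> tuple[pd.DataFrame, ScalingStats]:
    """Standardise columns as (x - mean) / sd with sample sd (n-1 denominator).

    When ``ref`` is absent the statistics are computed from ``matrix`` itself
    and returned for reuse on external compounds. Constant columns raise a
    :class:`ValidationError` naming the column.
    """
    matrix = matrix.astype(float)
    if ref is None:
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=1)
        constant = sd.index[(sd == 0) | sd.isna()].tolist()
        if constant:
            raise ValidationError(f"constant column(s): {constant}")
        ref = ScalingStats(mean=mean, sd=sd)
    return ref.apply(matrix), ref


class MACCSFingerprinter(BaseEstimator, TransformerMixin):
    """Transformer from cleaned SMILES to retained MACCS key bits.

    ``fit`` learns which of the 166 keys are present in more than
    ``min_count`` training compounds; ``transform`` returns the binary matrix
    restricted to those keys.

    Attributes
    ----------
    retained_keys_ : list of int
        1-based key numbers kept after frequency selection.
    training_matrix_ : FingerprintMatrix
        Training fingerprints, kept for applicability-domain distances.
    """

    def __init__(self, min_count: int = 5):
        self.min_count = min_count

    def fit(self, X: Sequence[str], y=None) -> "MACCSFingerprinter":
        ids = [str(i) for i in range(len(X))]
        fp = fingerprint_matrix(ids, list(X))
        fp.retained_keys = select_frequent_keys(fp, self.min_count)
        self.retained_keys_ = fp.retained_keys
        self.training_matrix_ = fp
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        if not hasattr(self, "retained_keys_"):
            raise ValidationError("MACCSFingerprinter is not fitted")
        bits = np.vstack([maccs_fingerprint(s) for s in X])
        return bits[:, [k - 1 for k in self.retained_keys_]]

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([f"MACCS_{k}" for k in self.retained_keys_])


class PhyschemDescriptors(BaseEstimator, TransformerMixin):
    """Transformer from cleaned SMILES to a physicochemical descriptor matrix.

    ``columns`` selects which descriptors to emit (default: the nine used by
    the weed-selectivity models). Stateless; ``fit`` only validates.
    """

    def __init__(self, columns: Sequence[str] = NINE_DESCRIPTORS):
        self.columns = columns

    def fit(self, X: Sequence[str], y=None) -> "PhyschemDescriptors":
        unknown = [c for c in self.columns if c not in DESCRIPTOR_NAMES]
        if unknown:
            raise ConfigurationError(f"unknown descriptor(s) {unknown}")
        self.columns_ = list(self.columns)
        return self

    def transform(self, X: Sequence[str]) -> pd.DataFrame:
        ids = [str(i) for i in range(len(X))]
        return physchem_table(ids, list(X))[list(self.columns)].reset_index(drop=True)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.columns, dtype=object)


class DescriptorScaler(BaseEstimator, TransformerMixin):
    """(x - mean) / sd standardisation with sample (n-1) standard deviation.

    Thin estimator around :func:`scale_columns`; refuses constant columns and
    exposes the learned statistics as ``stats_`` for persistence and for
    scaling external query compounds.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "DescriptorScaler":
        _, self.stats_ = scale_columns(pd.DataFrame(X))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "stats_"):
            raise ValidationError("DescriptorScaler is not fitted")
        scaled, _ = scale_columns(pd.DataFrame(X), self.stats_)
        return scaled
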