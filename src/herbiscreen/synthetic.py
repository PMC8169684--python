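"""Synthetic labelled compound sets for exercising the full pipeline.

Real herbicide collections cluster by shared scaffolds within a mode-of-action
class, and weed-selectivity classes differ in physicochemical profile
(non-selective compounds polar and hydrophilic, grass-selective compounds
lipophilic with few H-bond donors, broadleaf-selective compounds small with
about one donor). The generators emulate both regularities by decorating
scaffolds with random substituents:

* :func:`generate_scaffold_classes` gives each class its own scaffold, so
  classes are structurally separable in MACCS-key space;
* :func:`generate_selectivity_set` shares scaffolds across classes and biases
  the substituent pool per class instead, so separation lives in the
  descriptor space, not the fingerprints.

Decoration counts are Poisson-distributed and positions chosen uniformly over
chemically safe sites, so every emitted SMILES is a valid, already-clean
canonical structure. All randomness flows from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import CompoundRecord, CompoundSet
from .errors import ConfigurationError

#: one distinctive scaffold per mode-of-action-style class
MOA_SCAFFOLDS: tuple[str, ...] = (
    "c1ccc(Oc2ccccc2)cc1",          # diphenyl ether
    "O=C(Nc1ccccc1)Nc1ccccc1",      # phenylurea
    "O=S(=O)(Nc1ccccc1)c1ccccc1",   # sulfonanilide
    "c1ccc2nccnc2c1",               # quinoxaline
    "c1ccc2scnc2c1",                # benzothiazole
    "c1ccc2[nH]ncc2c1",             # indazole
    "c1ccc(-c2ccccc2)cc1",          # biphenyl
    "c1ccc(Cc2ccccc2)cc1",          # diphenylmethane
    "c1ccc(-n2ccnc2)cc1",           # phenylimidazole
    "c1ccc2ccccc2c1",               # naphthalene
)

#: scaffolds shared across selectivity classes (no structural signal)
SELECTIVITY_SCAFFOLDS: tuple[str, ...] = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "c1ccc(-c2ccccc2)cc1",
    "c1ccc(Oc2ccccc2)cc1",
)

#: scaffold families foreign to both default libraries, for AD stress tests
NOVEL_SCAFFOLDS: tuple[str, ...] = (
    "C1CCCCCCCCCCC1",               # cyclododecane
    "C1C2CC3CC1CC(C2)C3",           # adamantane
    "C1COCCOCCOCCO1",               # 12-crown-4 macrocycle
    "C1CCC2(CC1)OCCO2",             # spiro ketal
)

_MOA_LABELS = ("A", "B", "C1", "E", "F2", "K1", "O", "M", "K3", "D")

# substituents as fragment SMILES whose first atom is the attachment point
_NEUTRAL_POOL = ("C", "Cl", "F", "OC", "O", "CC", "N", "C(F)(F)F")
_NS_POOL = ("O", "N", "C(=O)O", "C(N)=O", "S(N)(=O)=O", "CO")      # polar
_G_POOL = ("Cl", "C(F)(F)F", "CC", "CCC", "Br", "C", "CCCC")       # lipophilic
_BL_POOL = ("C", "F", "Cl")                                        # small, apolar

#: per-class substituent pools, decoration rates, guaranteed substituents
#: ("base") and scaffold subsets realising the selectivity-class contrasts:
#: NS polar/hydrophilic with many acceptors and ~2 donors, G lipophilic with
#: no donors, BL small with exactly about one donor.
DEFAULT_SELECTIVITY_SHIFTS: dict[str, dict] = {
    "NS": {"pool": _NS_POOL, "rate": 3.0, "base": ("O", "C(N)=O")},
    "G": {"pool": _G_POOL, "rate": 2.5},
    "BL": {"pool": _BL_POOL, "rate": 1.2, "base": ("O",),
           "scaffolds": ("c1ccccc1", "c1ccncc1")},
}


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic compound set.

    ``descriptor_shifts`` maps a class label to ``{"pool": [...], "rate": x}``
    — the substituent pool and expected substituent count realising that
    class's descriptor profile. ``None`` selects the built-in defaults; an
    empty mapping makes all classes draw from one neutral pool (the null
    condition with no class signal in the descriptors).
    """

    n_classes: int = 8
    n_per_class: int = 30
    scaffold_library: Sequence[str] = MOA_SCAFFOLDS
    decoration_rate: float = 1.5
    descriptor_shifts: Mapping[str, Mapping] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decoration_rate < 0:
            raise ConfigurationError("decoration_rate must be >= 0")
        if self.n_classes < 1 or self.n_per_class < 1:
            raise ConfigurationError("n_classes and n_per_class must be >= 1")


def _parse_scaffold(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ConfigurationError(f"unparseable scaffold {smiles!r}")
    return mol


def _open_positions(mol: Chem.Mol) -> list[int]:
    """Carbon atoms that can take one more substituent without valence issues."""
    positions = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6:
            continue
        needed = 1 if atom.GetIsAromatic() else 2
        if atom.GetTotalNumHs() >= needed:
            positions.append(atom.GetIdx())
    return positions


def decorate_scaffold(
    scaffold_smiles: str,
    substituents: Sequence[str],
    n_substituents: int,
    rng: np.random.Generator,
    base: Sequence[str] = (),
) -> str:
    """Attach substituents at random open positions of a scaffold.

    Every fragment in ``base`` is attached exactly once (guaranteed groups,
    e.g. the single H-bond donor of a class profile), then ``n_substituents``
    random draws from ``substituents`` follow. The total is capped by the
    number of available positions. Returns the canonical SMILES.
    """
    mol = _parse_scaffold(scaffold_smiles)
    frags = list(base) + [
        substituents[int(rng.integers(len(substituents)))]
        for _ in range(n_substituents)
    ]
    for frag_smiles in frags:
        positions = _open_positions(mol)
        if not positions:
            break
        site = positions[int(rng.integers(len(positions)))]
        frag = _parse_scaffold(frag_smiles)
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        Chem.SanitizeMol(combined)
        mol = combined.GetMol()
    return Chem.MolToSmiles(mol)


def generate_from_scaffolds(
    scaffolds: Sequence[str],
    n: int,
    pool: Sequence[str],
    rate: float,
    rng: np.random.Generator,
    id_prefix: str = "cmpd",
    base: Sequence[str] = (),
    **record_fields,
) -> list[CompoundRecord]:
    """n decorated molecules drawn from a scaffold list and substituent pool."""
    records = []
    for j in range(n):
        scaffold = scaffolds[int(rng.integers(len(scaffolds)))]
        smiles = decorate_scaffold(
            scaffold, pool, int(rng.poisson(rate)), rng, base=base
        )
        records.append(
            CompoundRecord(
                id=f"{id_prefix}_{j:04d}", smiles_raw=smiles,
                smiles_clean=smiles, **record_fields,
            )
        )
    return records


def generate_scaffold_classes(spec: SyntheticSpec) -> CompoundSet:
    """Structurally separable classes: one scaffold per mode-of-action label.

    Deterministic for a given spec and seed; every record carries an
    MoA-style label and an already-canonical cleaned SMILES.
    """
    if spec.n_classes > len(spec.scaffold_library):
        raise ConfigurationError(
            f"n_classes ({spec.n_classes}) exceeds scaffold library size "
            f"({len(spec.scaffold_library)})"
        )
    for s in spec.scaffold_library[: spec.n_classes]:
        _parse_scaffold(s)
    rng = np.random.default_rng(spec.seed)
    records: list[CompoundRecord] = []
    for ci in range(spec.n_classes):
        label = _MOA_LABELS[ci % len(_MOA_LABELS)]
        records.extend(
            generate_from_scaffolds(
                [spec.scaffold_library[ci]], spec.n_per_class,
                _NEUTRAL_POOL, spec.decoration_rate, rng,
                id_prefix=f"moa{ci}_{label}",
                moa_label=label, origin="synthetic",
            )
        )
    return CompoundSet(records, provenance=f"synthetic scaffold classes seed={spec.seed}")


def generate_selectivity_set(spec: SyntheticSpec) -> CompoundSet:
    """BL/G/NS classes separated in descriptor space, not structure.

    All classes draw scaffolds from the same library; the per-class
    substituent pools shift the computed descriptor distributions (NS: polar,
    many acceptors, low clogP; G: lipophilic, few donors; BL: small, about
    one donor). With ``descriptor_shifts={}`` all classes share one neutral
    pool and carry no descriptor signal.
    """
    shifts = spec.descriptor_shifts
    if shifts is None:
        shifts = DEFAULT_SELECTIVITY_SHIFTS
    default_scaffolds = (
        spec.scaffold_library if spec.scaffold_library is not MOA_SCAFFOLDS
        else SELECTIVITY_SCAFFOLDS
    )
    rng = np.random.default_rng(spec.seed)
    records: list[CompoundRecord] = []
    for label in ("BL", "G", "NS"):
        cfg = shifts.get(label, {})
        pool = tuple(cfg.get("pool", _NEUTRAL_POOL))
        rate = float(cfg.get("rate", spec.decoration_rate))
        base = tuple(cfg.get("base", ()))
        scaffolds = tuple(cfg.get("scaffolds", default_scaffolds))
        if rate < 0:
            raise ConfigurationError(f"negative decoration rate for class {label}")
        for frag in pool + base + scaffolds:
            _parse_scaffold(frag)
        records.extend(
            generate_from_scaffolds(
                scaffolds, spec.n_per_class, pool, rate, rng,
                id_prefix=f"sel_{label}", base=base,
                selectivity_label=label, origin="synthetic",
            )
        )
    return CompoundSet(records, provenance=f"synthetic selectivity set seed={spec.seed}")


def generate_novel_scaffold_set(
    n: int, seed: int = 0, scaffolds: Sequence[str] = NOVEL_SCAFFOLDS
) -> CompoundSet:
    """Compounds from scaffold families absent from the default libraries.

    Used to probe applicability-domain rejection of structurally foreign
    chemistry (the natural-product situation).
    """
    rng = np.random.default_rng(seed)
    records = generate_from_scaffolds(
        scaffolds, n, _NEUTRAL_POOL, 1.5, rng,
        id_prefix="novel", origin="other",
    )
    return CompoundSet(records, provenance=f"synthetic novel scaffolds seed={seed}")
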