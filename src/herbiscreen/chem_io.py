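"""Compound table I/O, structure cleaning and label vocabularies.

Compound sets are ordered collections of :class:`CompoundRecord`, each holding
a raw SMILES, its cleaned canonical form and optional categorical labels:
mode of action (HRAC legacy letter codes), weed selectivity (BL / G / NS),
application stage (PRE / POST / BOTH) and compound origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

from .errors import ConfigurationError, StructureError, ValidationError

RDLogger.DisableLog("rdApp.*")

#: HRAC legacy mode-of-action codes; "Z" collects unclassified compounds.
MOA_VOCAB: tuple[str, ...] = (
    "A", "B", "C1", "C2", "C3", "D", "E", "F1", "F2", "F3", "F4",
    "G", "H", "I", "K1", "K2", "K3", "L", "M", "N", "O", "P", "Z",
)
SELECTIVITY_VOCAB: tuple[str, ...] = ("BL", "G", "NS")
STAGE_VOCAB: tuple[str, ...] = ("PRE", "POST", "BOTH")
ORIGIN_VOCAB: tuple[str, ...] = ("synthetic", "bacterial", "fungal", "plant", "other")

_LABEL_VOCABS = {
    "moa_label": MOA_VOCAB,
    "selectivity_label": SELECTIVITY_VOCAB,
    "stage_label": STAGE_VOCAB,
    "origin": ORIGIN_VOCAB,
}

# Cations with hydrogens (not bonded to an anion) and anions (not bonded to a
# cation) are neutralisable; permanently charged centres such as quaternary
# ammonium fall outside this pattern and are kept charged.
_NEUTRALIZE = Chem.MolFromSmarts(
    "[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]"
)


@dataclass(frozen=True)
class CompoundRecord:
    """One compound with identifier, structures and optional labels."""

    id: str
    smiles_raw: str
    smiles_clean: str | None = None
    moa_label: str | None = None
    selectivity_label: str | None = None
    stage_label: str | None = None
    origin: str | None = None
    extra_descriptors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("compound id must be non-empty")
        for fname, vocab in _LABEL_VOCABS.items():
            value = getattr(self, fname)
            if value is not None and value not in vocab:
                raise ValidationError(
                    f"label {value!r} for {fname} not in vocabulary {vocab}"
                )


@dataclass
class CompoundSet:
    """Ordered, id-unique collection of compound records."""

    records: list[CompoundRecord]
    provenance: str = ""
    #: rows rejected at load time (unparseable SMILES), one row per rejection
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "smiles_raw", "reason"])
    )

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate compound ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def smiles(self, clean: bool = True) -> list[str]:
        """Cleaned (default) or raw structure strings, in record order."""
        if clean:
            return [r.smiles_clean if r.smiles_clean is not None else r.smiles_raw
                    for r in self.records]
        return [r.smiles_raw for r in self.records]

    def labels(self, field_name: str) -> list[str | None]:
        if field_name not in _LABEL_VOCABS:
            raise ValidationError(f"unknown label field {field_name!r}")
        return [getattr(r, field_name) for r in self.records]

    def subset(self, keep_ids: Iterable[str]) -> "CompoundSet":
        keep = set(keep_ids)
        return CompoundSet(
            [r for r in self.records if r.id in keep], provenance=self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "id": r.id,
                "smiles_raw": r.smiles_raw,
                "smiles_clean": r.smiles_clean,
                "moa_label": r.moa_label,
                "selectivity_label": r.selectivity_label,
                "stage_label": r.stage_label,
                "origin": r.origin,
            }
            row.update(r.extra_descriptors)
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        """Write the set as a UTF-8 comma-separated table with header."""
        self.to_frame().to_csv(path, index=False)


def clean_structure(smiles_raw: str) -> str:
    """Clean a raw SMILES to a canonical, desalted, neutralised form.

    The largest organic fragment is retained (counter-ions stripped; ties on
    heavy-atom count broken by lexicographic canonical SMILES), formal charges
    are neutralised where a neutral form exists, and the RDKit canonical
    SMILES is returned. Permanently charged centres (e.g. quaternary
    ammonium, as in bipyridinium herbicides) are kept charged with a warning.

    Raises
    ------
    StructureError
        If the string is empty or does not parse.
    """
    if not smiles_raw or not smiles_raw.strip():
        raise StructureError(smiles_raw, "empty structure string")
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise StructureError(smiles_raw, "unparseable SMILES")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        def frag_key(m: Chem.Mol) -> tuple:
            has_carbon = any(a.GetAtomicNum() == 6 for a in m.GetAtoms())
            return (has_carbon, m.GetNumHeavyAtoms(), _neg(Chem.MolToSmiles(m)))
        mol = max(frags, key=frag_key)

    mol = _neutralize(mol)
    if Chem.GetFormalCharge(mol) != 0:
        warnings.warn(
            f"structure {smiles_raw!r} carries a permanent net charge "
            f"{Chem.GetFormalCharge(mol)}; kept charged",
            stacklevel=2,
        )
    return Chem.MolToSmiles(mol)


class _neg(str):
    # invert string ordering so max() picks the lexicographically smallest
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    matches = mol.GetSubstructMatches(_NEUTRALIZE)
    if not matches:
        return mol
    mol = Chem.RWMol(mol)
    for (idx,) in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        n_h = atom.GetTotalNumHs()
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(n_h - charge)
        atom.UpdatePropertyCache()
    Chem.SanitizeMol(mol)
    return mol.GetMol()


def mol_from_clean_smiles(smiles: str) -> Chem.Mol:
    """Parse a cleaned SMILES, raising :class:`StructureError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(smiles, "unparseable SMILES")
    return mol


def load_compound_table(
    path: str | Path,
    column_mapping: Mapping[str, str] | None = None,
    provenance: str | None = None,
    extra_descriptor_columns: Sequence[str] = (),
) -> CompoundSet:
    """Load a compound CSV, cleaning structures row by row.

    ``column_mapping`` maps record fields (``id``, ``smiles``, and optionally
    ``moa_label``, ``selectivity_label``, ``stage_label``, ``origin``) to CSV
    column names; ``{"id": "id", "smiles": "smiles_raw"}`` is the default.
    Rows whose SMILES fail to parse are collected into ``result.rejections``
    rather than silently dropped. Labels outside the declared vocabularies are
    mapped to "Z" (mode of action) or dropped (other fields) with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    mapping = dict(column_mapping or {"id": "id", "smiles": "smiles_raw"})
    for required in ("id", "smiles"):
        if required not in mapping:
            raise ConfigurationError(f"column_mapping must name a {required!r} column")
    try:
        table = pd.read_csv(path, dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty compound table: {path}") from exc
    if table.empty:
        raise ValidationError(f"compound table has no rows: {path}")
    for fname, col in mapping.items():
        if col not in table.columns:
            raise ConfigurationError(f"missing column {col!r} (mapped to {fname!r})")
    for col in extra_descriptor_columns:
        if col not in table.columns:
            raise ConfigurationError(f"missing descriptor column {col!r}")

    ids = table[mapping["id"]].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"duplicate compound ids: {dupes}")

    records: list[CompoundRecord] = []
    rejected: list[dict] = []
    for _, row in table.iterrows():
        cid = row[mapping["id"]]
        raw = row[mapping["smiles"]]
        if not isinstance(raw, str) or not raw.strip():
            rejected.append({"id": cid, "smiles_raw": raw, "reason": "missing SMILES"})
            continue
        try:
            clean = clean_structure(raw)
        except StructureError as exc:
            rejected.append({"id": cid, "smiles_raw": raw, "reason": exc.args[-1]})
            continue
        labels: dict[str, str | None] = {}
        for fname in ("moa_label", "selectivity_label", "stage_label", "origin"):
            col = mapping.get(fname)
            value = row[col] if col else None
            if isinstance(value, str) and value.strip():
                value = value.strip()
                if value not in _LABEL_VOCABS[fname]:
                    fallback = "Z" if fname == "moa_label" else None
                    warnings.warn(
                        f"unknown {fname} {value!r} for compound {cid}; "
                        f"mapped to {fallback!r}",
                        stacklevel=2,
                    )
                    value = fallback
                labels[fname] = value
            else:
                labels[fname] = None
        extras = {
            col: float(row[col])
            for col in extra_descriptor_columns
            if isinstance(row[col], str) and row[col].strip()
        }
        records.append(
            CompoundRecord(
                id=cid, smiles_raw=raw, smiles_clean=clean,
                extra_descriptors=extras, **labels,
            )
        )
    result = CompoundSet(records, provenance=provenance or str(path))
    result.rejections = pd.DataFrame(
        rejected, columns=["id", "smiles_raw", "reason"]
    )
    return result


def compound_set_from_frame(frame: pd.DataFrame, provenance: str = "") -> CompoundSet:
    """Rebuild a :class:`CompoundSet` from :meth:`CompoundSet.to_frame` output."""
    core = {"id", "smiles_raw", "smiles_clean",
            "moa_label", "selectivity_label", "stage_label", "origin"}
    records = []
    for _, row in frame.iterrows():
        extras = {
            k: float(v) for k, v in row.items()
            if k not in core and pd.notna(v)
        }
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                smiles_raw=str(row["smiles_raw"]),
                smiles_clean=None if pd.isna(row.get("smiles_clean")) else str(row["smiles_clean"]),
                moa_label=_opt(row.get("moa_label")),
                selectivity_label=_opt(row.get("selectivity_label")),
                stage_label=_opt(row.get("stage_label")),
                origin=_opt(row.get("origin")),
                extra_descriptors=extras,
            )
        )
    return CompoundSet(records, provenance=provenance)


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return str(value)


def relabel(record: CompoundRecord, **changes) -> CompoundRecord:
    """Return a copy of ``record`` with the given fields replaced."""
    return replace(record, **changes)
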