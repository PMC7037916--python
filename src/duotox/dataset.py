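"""Toxicity records, the packaged quinolone dataset, and structure/property readers.

The packaged fixture holds the 50-compound dual-endpoint dataset (green-algae
``p_ec50``, bacterial-genotoxicity ``p_loec``, published composite value and
train/test split).  Structures are user-supplied as SDF, MOL2 or SMILES;
externally computed properties (DFT energies, logKow, half-lives, docking
scores) arrive as plain CSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import FixtureIntegrityError, InputError, UsageError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

#: closed set of external property names accepted by :func:`read_property_table`
PROPERTY_NAMES = frozenset(
    {
        "frequency",
        "total_energy",
        "log_kow",
        "t_half_river",
        "dock_total_score",
        "dock_binding_energy",
    }
)

_FIXTURE_COLUMNS = ["no", "compound_id", "name", "p_ec50", "p_loec", "composite", "split", "flag"]


@dataclass
class ToxicityRecord:
    """One compound's endpoint values and (optionally) its composite value."""

    compound_id: str
    name: str
    p_ec50: float
    p_loec: float
    composite: float | None = None
    split: str | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.p_ec50) or not math.isfinite(self.p_loec):
            raise InputError(f"{self.compound_id}: endpoint values must be finite")
        if self.split is not None and self.split not in ("train", "test"):
            raise InputError(f"{self.compound_id}: split must be 'train' or 'test'")


@dataclass
class ExternalPropertyRecord:
    """One externally computed property value for one compound."""

    compound_id: str
    property_name: str
    value: float
    context: str = ""

    def __post_init__(self) -> None:
        if self.property_name not in PROPERTY_NAMES:
            raise InputError(
                f"unknown property {self.property_name!r}; "
                f"expected one of {sorted(PROPERTY_NAMES)}"
            )
        if not math.isfinite(self.value):
            raise InputError(f"{self.compound_id}/{self.property_name}: value must be finite")


@dataclass
class Dataset:
    """A set of toxicity records plus optional structures."""

    records: list[ToxicityRecord]
    molecules: dict[str, Chem.Mol] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.compound_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise InputError("duplicate compound_id in dataset")
        unknown = set(self.molecules) - set(ids)
        if unknown:
            raise InputError(f"molecules without a matching record: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, compound_id: str) -> ToxicityRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)

    def subset(self, split: str) -> list[ToxicityRecord]:
        return [r for r in self.records if r.split == split]

    def with_records(self, records: Iterable[ToxicityRecord]) -> "Dataset":
        return Dataset(records=list(records), molecules=dict(self.molecules), provenance=self.provenance)


def _normalize_minus(text: str) -> str:
    # U+2212 (minus) and U+2013 (en dash) appear in typeset tables
    return text.replace("−", "-").replace("–", "-")


def load_table1_fixture() -> Dataset:
    """Load the packaged 50-compound dual-endpoint dataset.

    Returns the records with their published composite values and the
    published 40/10 train/test partition.  Row 50 carries the ``inconsistent``
    flag: its published composite disagrees in sign with the documented
    composite formula and is excluded from reproduction checks downstream.
    """
    with resources.files("duotox.data").joinpath("quinolone_toxicity.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        frame = pd.read_csv(fh, dtype={"flag": "string"})
    if list(frame.columns) != _FIXTURE_COLUMNS:
        raise FixtureIntegrityError(f"unexpected fixture columns: {list(frame.columns)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            ToxicityRecord(
                compound_id=str(row.compound_id),
                name=str(row.name),
                p_ec50=float(row.p_ec50),
                p_loec=float(row.p_loec),
                composite=float(row.composite),
                split=str(row.split),
                flag=None if pd.isna(row.flag) else str(row.flag),
            )
        )
    ds = Dataset(records=records, provenance="packaged fixture quinolone_toxicity.csv")
    n_test = sum(1 for r in records if r.split == "test")
    if len(records) != 50 or n_test != 10:
        raise FixtureIntegrityError(
            f"fixture must hold 50 records with 10 test rows, got {len(records)}/{n_test}"
        )
    return ds


def write_toxicity_table(dataset: Dataset, path: str | Path) -> None:
    """Write records to CSV in the same layout the fixture uses."""
    rows = [
        {
            "no": i + 1,
            "compound_id": r.compound_id,
            "name": r.name,
            "p_ec50": r.p_ec50,
            "p_loec": r.p_loec,
            "composite": r.composite,
            "split": r.split,
            "flag": r.flag,
        }
        for i, r in enumerate(dataset.records)
    ]
    pd.DataFrame(rows, columns=_FIXTURE_COLUMNS).to_csv(path, index=False)


def read_toxicity_table(path: str | Path) -> Dataset:
    """Read a toxicity CSV written by :func:`write_toxicity_table` (or hand-made)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path, dtype={"flag": "string"})
    required = {"compound_id", "p_ec50", "p_loec"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"toxicity table missing columns: {sorted(missing)}")
    records = []
    for row in frame.to_dict("records"):
        records.append(
            ToxicityRecord(
                compound_id=str(row["compound_id"]),
                name=str(row.get("name", row["compound_id"])),
                p_ec50=float(_normalize_minus(str(row["p_ec50"]))),
                p_loec=float(_normalize_minus(str(row["p_loec"]))),
                composite=None if pd.isna(row.get("composite")) else float(row["composite"]),
                split=None if pd.isna(row.get("split")) else str(row["split"]),
                flag=None if pd.isna(row.get("flag")) else str(row["flag"]),
            )
        )
    return Dataset(records=records, provenance=str(path))


def resplit(dataset: Dataset, n_test: int, seed: int) -> Dataset:
    """Optional seeded re-randomization of the train/test partition."""
    import numpy as np

    if not 0 < n_test < len(dataset):
        raise UsageError("n_test must be between 1 and len(dataset)-1")
    rng = np.random.default_rng(seed)
    test_idx = set(rng.choice(len(dataset), size=n_test, replace=False).tolist())
    records = [
        replace(r, split="test" if i in test_idx else "train")
        for i, r in enumerate(dataset.records)
    ]
    return dataset.with_records(records)


# ---------------------------------------------------------------------------
# structure input
# ---------------------------------------------------------------------------


def _iter_mol2_blocks(text: str) -> Iterable[str]:
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    for part in parts[1:]:
        yield marker + part


def read_structures(path: str | Path, format: str | None = None) -> dict[str, Chem.Mol]:
    """Read molecules from an SDF, MOL2 or SMILES file, keyed by name.

    Per-entry parse failures are logged and skipped; only a file with zero
    parsable entries is an error.  Hydrogens are made explicit.  Existing 3D
    coordinates are preserved.
    """
    path = Path(path)
    if format is None:
        format = {".sdf": "sdf", ".sd": "sdf", ".mol2": "mol2", ".smi": "smiles", ".smiles": "smiles"}.get(
            path.suffix.lower(), ""
        )
    if format not in ("sdf", "mol2", "smiles"):
        raise UsageError(f"unknown structure format {format!r}; use sdf, mol2 or smiles")
    if not path.exists():
        raise InputError(f"no such file: {path}")

    molecules: dict[str, Chem.Mol] = {}
    n_entries = 0

    def _add(mol: Chem.Mol | None, fallback_name: str) -> None:
        if mol is None:
            logger.warning("skipping unparsable entry %s in %s", fallback_name, path)
            return
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else fallback_name
        add_coords = mol.GetNumConformers() > 0
        molH = Chem.AddHs(mol, addCoords=add_coords)
        molH.SetProp("_Name", name)
        molecules[name] = molH

    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            n_entries += 1
            _add(mol, f"entry_{i}")
    elif format == "mol2":
        text = path.read_text()
        for i, block in enumerate(_iter_mol2_blocks(text)):
            n_entries += 1
            mol = Chem.MolFromMol2Block(block, removeHs=False, sanitize=True)
            _add(mol, f"entry_{i}")
    else:  # smiles: "SMILES name" per line
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_entries += 1
            tokens = line.split(None, 1)
            mol = Chem.MolFromSmiles(tokens[0])
            name = tokens[1].strip() if len(tokens) > 1 else f"entry_{i}"
            if mol is not None:
                mol.SetProp("_Name", name)
            _add(mol, name)

    if n_entries == 0:
        raise InputError(f"{path}: file contains no entries")
    if not molecules:
        raise InputError(f"{path}: no entry could be parsed")
    return molecules


def read_property_table(path: str | Path) -> list[ExternalPropertyRecord]:
    """Read externally computed property values (CSV) into typed records."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    frame = pd.read_csv(path)
    if "compound_id" not in frame.columns:
        raise InputError("property table must have a compound_id column")
    for col in ("property_name", "value"):
        if col not in frame.columns:
            raise InputError(f"property table must have a {col} column")
    records = []
    for row in frame.to_dict("records"):
        records.append(
            ExternalPropertyRecord(
                compound_id=str(row["compound_id"]),
                property_name=str(row["property_name"]),
                value=float(_normalize_minus(str(row["value"]))),
                context="" if pd.isna(row.get("context", "")) else str(row.get("context", "")),
            )
        )
    return records


def property_lookup(
    records: Iterable[ExternalPropertyRecord],
) -> Mapping[tuple[str, str, str], float]:
    """Index property records by (compound_id, property_name, context)."""
    return {(r.compound_id, r.property_name, r.context): r.value for r in records}


def load_derivative_toxicity() -> pd.DataFrame:
    """Packaged raw EC50/LOEC values for the parent compound and its three derivatives."""
    with resources.files("duotox.data").joinpath("derivative_toxicity.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


def load_derivative_composites() -> pd.DataFrame:
    """Packaged predicted composite values for the parent and derivatives."""
    with resources.files("duotox.data").joinpath("derivative_composites.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return pd.read_csv(fh)


def load_derivative_properties() -> list[ExternalPropertyRecord]:
    """Packaged external property values (DFT, EPI, docking) for the derivatives."""
    with resources.as_file(
        resources.files("duotox.data").joinpath("derivative_properties.csv")
    ) as p:
        return read_property_table(p)
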