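"""Molecule tables, descriptor calculation and dataset partitioning.

Molecules enter as CSV (id, SMILES, optional observed logPe in
log10(cm/s)) or SDF with 3D coordinates.  Descriptors are computed with
RDKit: the full 2D descriptor set (~210 named descriptors, including the
BCUT2D family) and, optionally, the 3D shape descriptors from a single
distance-geometry conformer embedded with a fixed seed.  Geometry
descriptors are conformer-dependent and should be treated as such.

The historical reference descriptor engine for this kind of permeability
model is the CDK; its descriptor set is version-dependent and is not
reproduced here.  ``CDK_NAME_MAP`` documents the correspondence between
frequently cited CDK descriptor names and their nearest RDKit
counterparts; CPSA-family descriptors (e.g. FNSA.3) have no RDKit
equivalent and are absent from the map.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Descriptors, Descriptors3D

__all__ = [
    "MoleculeRecord",
    "DescriptorTable",
    "ScalingParams",
    "DataSplit",
    "CDK_NAME_MAP",
    "read_molecule_table",
    "write_molecule_table",
    "compute_descriptors",
    "drop_zero_variance",
    "drop_nonfinite_columns",
    "correlation_screen",
    "fit_minmax_scaler",
    "apply_minmax_scaler",
    "split_dataset",
]

RDLogger.DisableLog("rdApp.*")

#: Nearest-RDKit names for commonly cited CDK descriptors.  Approximate:
#: descriptor *semantics* match, numerical values are engine-specific.
CDK_NAME_MAP = {
    "nHBDon": "NumHDonors",
    "nHBAcc": "NumHAcceptors",
    "TopoPSA": "TPSA",
    "XLogP": "MolLogP",
    "ALogP": "MolLogP",
    "nAcid": "fr_COO",
    "MW": "MolWt",
    "nRotB": "NumRotatableBonds",
    "BCUTw.1h": "BCUT2D_MWHI",
    "BCUTw.1l": "BCUT2D_MWLOW",
    "BCUTc.1h": "BCUT2D_CHGHI",
    "BCUTc.1l": "BCUT2D_CHGLO",
    "BCUTp.1h": "BCUT2D_LOGPHI",
    "BCUTp.1l": "BCUT2D_LOGPLOW",
    "tpsaEfficiency": None,  # TPSA per unit molecular surface; no RDKit analogue
    "FNSA.3": None,  # charged partial surface area family; no RDKit analogue
    "MDEO.11": None,  # molecular distance-edge on O-O; no RDKit analogue
}

_PARTITIONS = ("train", "test", "external", "unassigned")


@dataclass
class MoleculeRecord:
    """One compound: identifier, structure and optional measured logPe."""

    id: str
    smiles: str
    log_pe: float | None = None
    partition: str = "unassigned"

    def __post_init__(self):
        if not self.id:
            raise ValueError("molecule id must be non-empty")
        if self.partition not in _PARTITIONS:
            raise ValueError(f"partition must be one of {_PARTITIONS}")


@dataclass
class DescriptorTable:
    """Molecules × named descriptors, with descriptor-engine provenance."""

    data: pd.DataFrame  # index: molecule ids; columns: descriptor names
    backend: str

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate descriptor names: {dupes}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate molecule ids")

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_csv(self, path, provenance_path=None) -> None:
        self.data.to_csv(path, index_label="id")
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                json.dump({"backend": self.backend,
                           "n_molecules": len(self.data),
                           "n_descriptors": self.data.shape[1]}, fh, indent=2)

    @classmethod
    def from_csv(cls, path, backend="unknown", provenance_path=None) -> "DescriptorTable":
        if provenance_path is not None:
            with open(provenance_path) as fh:
                backend = json.load(fh).get("backend", backend)
        df = pd.read_csv(path, index_col="id")
        df.index = df.index.astype(str)
        return cls(df, backend)


@dataclass
class ScalingParams:
    """Column-wise min/max fitted on the training table for 0–1 scaling."""

    names: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    fitted_on: str = ""

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.mins > self.maxs):
            raise ValueError("per-descriptor min must not exceed max")

    @property
    def constant(self) -> np.ndarray:
        """Boolean mask of descriptors with min == max (flagged constant)."""
        return self.mins == self.maxs


@dataclass
class DataSplit:
    """Disjoint external / train / test molecule-id assignment."""

    external_ids: list[str]
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self):
        groups = (set(self.external_ids), set(self.train_ids), set(self.test_ids))
        if sum(len(g) for g in groups) != len(set().union(*groups)):
            raise ValueError("split groups are not pairwise disjoint")


# ---------------------------------------------------------------------------
# IO


def read_molecule_table(
    path,
    format: str = "csv",
    id_column: str = "id",
    smiles_column: str = "smiles",
    logpe_column: str = "logPe",
) -> list[MoleculeRecord]:
    """Load molecule records from CSV or SDF, rejecting unparsable SMILES.

    Rows whose SMILES RDKit cannot parse are excluded with a warning.
    Raises if the file is missing, no record parses, or ids collide.
    """
    if format == "csv":
        df = pd.read_csv(path)
        for col in (id_column, smiles_column):
            if col not in df.columns:
                raise ValueError(f"column {col!r} not found in {path}")
        records = []
        for _, row in df.iterrows():
            smiles = str(row[smiles_column])
            if Chem.MolFromSmiles(smiles) is None:
                warnings.warn(f"skipping {row[id_column]!r}: unparsable SMILES {smiles!r}")
                continue
            log_pe = None
            if logpe_column in df.columns and pd.notna(row[logpe_column]):
                log_pe = float(row[logpe_column])
            records.append(MoleculeRecord(str(row[id_column]), smiles, log_pe))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        records = []
        for i, mol in enumerate(supplier):
            if mol is None:
                warnings.warn(f"skipping SDF entry {i}: unparsable molecule")
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
            log_pe = float(mol.GetProp(logpe_column)) if mol.HasProp(logpe_column) else None
            records.append(MoleculeRecord(mol_id, Chem.MolToSmiles(mol), log_pe))
    else:
        raise ValueError(f"unknown format {format!r}")

    if not records:
        raise ValueError(f"no parsable molecule records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule ids: {dupes}")
    return records


def write_molecule_table(records, path, logpe_column: str = "logPe") -> None:
    """Write records back to CSV preserving ids, SMILES and logPe exactly."""
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            logpe_column: [r.log_pe for r in records],
            "partition": [r.partition for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Descriptors


def _embed_conformer(mol, seed: int):
    mol3d = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol3d, params) != 0:
        return None
    return mol3d


def compute_descriptors(
    records,
    backend: str = "rdkit-2d",
    conformer_seed: int = 2024,
) -> DescriptorTable:
    """Compute named molecular descriptors for every record.

    ``backend="rdkit-2d"`` computes the full RDKit 2D descriptor set
    (topological, constitutional, electronic and hybrid descriptors,
    including BCUT2D).  ``backend="rdkit-3d"`` additionally embeds one
    ETKDG conformer per molecule (seeded) and appends the RDKit 3D shape
    descriptors.  Descriptors RDKit cannot evaluate for a molecule are
    recorded as NaN; remove them with :func:`drop_nonfinite_columns`.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    if backend not in ("rdkit-2d", "rdkit-3d"):
        raise ValueError(f"unknown descriptor backend {backend!r}")

    rows = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES for molecule {rec.id!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row = Descriptors.CalcMolDescriptors(mol, missingVal=float("nan"))
        if backend == "rdkit-3d":
            mol3d = _embed_conformer(mol, conformer_seed)
            for name, fn in Descriptors3D.descList:
                try:
                    row[name] = float(fn(mol3d)) if mol3d is not None else float("nan")
                except Exception:
                    row[name] = float("nan")
        rows.append(row)

    from rdkit import rdBase

    df = pd.DataFrame(rows, index=[r.id for r in records], dtype=float)
    return DescriptorTable(df, backend=f"{backend} (rdkit {rdBase.rdkitVersion})")


def drop_zero_variance(table: DescriptorTable):
    """Remove descriptors whose value is identical across all molecules.

    Returns ``(screened_table, removed_names)``.  NaN-containing columns
    are never treated as constant here.  Raises if nothing survives.
    """
    vals = table.data
    constant = (vals.nunique(dropna=False) <= 1) & vals.notna().all()
    removed = list(vals.columns[constant])
    kept = vals.loc[:, ~constant]
    if kept.shape[1] == 0:
        raise ValueError("all descriptor columns are constant")
    return DescriptorTable(kept, table.backend), removed


def drop_nonfinite_columns(table: DescriptorTable):
    """Remove descriptor columns containing any NaN/inf value.

    Returns ``(screened_table, removed_names)``.
    """
    finite = np.isfinite(table.data.to_numpy(dtype=float)).all(axis=0)
    removed = list(table.data.columns[~finite])
    return DescriptorTable(table.data.loc[:, finite], table.backend), removed


def correlation_screen(table: DescriptorTable, cutoff: float = 0.8):
    """Report descriptor pairs with |Pearson r| above ``cutoff``.

    Report only — no columns are removed; redundancy among descriptors is
    resolved downstream by recursive feature elimination.  Requires a
    finite table with no zero-variance columns (run the screens first).
    """
    if len(table.data) < 2:
        raise ValueError("need at least two molecules")
    vals = table.values
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values present; run drop_nonfinite_columns first")
    if np.any(vals.std(axis=0) == 0):
        raise ValueError("zero-variance column present; run drop_zero_variance first")
    corr = np.corrcoef(vals, rowvar=False)
    names = table.descriptor_names
    pairs = []
    iu = np.triu_indices(len(names), k=1)
    for i, j in zip(*iu):
        r = float(corr[i, j])
        if abs(r) > cutoff:
            pairs.append((names[i], names[j], r))
    return pairs


# ---------------------------------------------------------------------------
# Scaling


def fit_minmax_scaler(table: DescriptorTable, fitted_on: str = "train") -> ScalingParams:
    """Record column-wise min and max of the table for 0–1 normalisation."""
    vals = table.values
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values present; screen the table first")
    return ScalingParams(
        names=table.descriptor_names,
        mins=vals.min(axis=0),
        maxs=vals.max(axis=0),
        fitted_on=fitted_on,
    )


def apply_minmax_scaler(table: DescriptorTable, params: ScalingParams) -> DescriptorTable:
    """Scale ``(x − min)/(max − min)`` with the stored training parameters.

    Values on the fitted table land in [0, 1]; values on new data may fall
    outside that interval and are deliberately NOT clipped — out-of-range
    scaled descriptors are exactly the signal the applicability domain
    relies on.  Constant columns map to 0.
    """
    if table.descriptor_names != params.names:
        raise ValueError("descriptor names do not match the fitted scaling parameters")
    span = params.maxs - params.mins
    safe_span = np.where(span == 0, 1.0, span)
    scaled = (table.values - params.mins) / safe_span
    scaled[:, params.constant] = 0.0
    return DescriptorTable(
        pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns),
        table.backend,
    )


# ---------------------------------------------------------------------------
# Partitioning


def split_dataset(records, n_external: int = 16, n_test: int = 33, seed: int = 0) -> DataSplit:
    """Seeded uniformly-random external/test/train partition.

    The external set is drawn first and set aside for final validation;
    the remainder is split into test and train.  With the defaults on a
    190-molecule table this reproduces the 141/33/16 protocol sizes.
    Partition tags are written back onto the records.
    """
    records = list(records)
    n = len(records)
    if n_external + n_test >= n:
        raise ValueError(f"n_external + n_test = {n_external + n_test} must be < {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    external = sorted(order[:n_external].tolist())
    test = sorted(order[n_external:n_external + n_test].tolist())
    train = sorted(order[n_external + n_test:].tolist())
    for idx, tag in ((external, "external"), (test, "test"), (train, "train")):
        for i in idx:
            records[i].partition = tag
    return DataSplit(
        external_ids=[records[i].id for i in external],
        train_ids=[records[i].id for i in train],
        test_ids=[records[i].id for i in test],
        seed=seed,
    )
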