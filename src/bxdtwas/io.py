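"""Domain types and readers/writers for the tabular formats the pipeline touches.

Three file dialects are supported, all plain text:

* expression / phenotype tables — TSV, UTF-8, header row of strain names,
  first column the row identifier (gene or phenotype);
* ABR record tables — TSV with named columns ``strain, individual, sex,
  age_months, frequency_khz, threshold_db``, one row per mouse × frequency;
* gene sets — GMT (``name TAB description TAB member...``, one set per line).

Expression matrices must be complete: a missing or non-numeric cell is a load
error, never a silent NaN.  Phenotype tables are the one place missing values
are legal (empty string or ``NA``), because published strain phenotypes are
measured on overlapping but unequal strain panels.  Strain names are matched
exactly after trimming whitespace and upper-casing a leading ``bxd`` prefix;
there is no fuzzy matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "LoadError",
    "ExpressionMatrix",
    "AbrRecordTable",
    "StrainTraitVector",
    "GeneSet",
    "GeneSetCollection",
    "PhenotypeTable",
    "SyntheticTruth",
    "VALID_FREQUENCIES_KHZ",
    "normalize_strain_name",
    "read_expression",
    "write_expression",
    "read_abr_records",
    "write_abr_records",
    "read_gmt",
    "write_gmt",
    "read_phenotypes",
    "write_phenotypes",
    "read_trait",
    "write_trait",
]

#: ABR stimulus frequencies tested in the hearing protocol, in kHz.
VALID_FREQUENCIES_KHZ = (8.0, 16.0, 32.0)

#: Valid range for an ABR threshold in dB SPL.
THRESHOLD_RANGE_DB = (0.0, 120.0)


class Scale(str, Enum):
    """Expression scale: raw log2 intensities or the modified Z scale (2z + 8)."""

    RAW_LOG2 = "raw_log2"
    MODIFIED_Z = "modified_z"


class LoadError(ValueError):
    """Raised when a file violates the format contract; names the offending row/column."""


def normalize_strain_name(name: str) -> str:
    """Trim whitespace and upper-case a leading ``bxd`` prefix.

    ``" bxd101 "`` -> ``"BXD101"``.  Anything beyond this is left alone:
    silent fuzzy joins are worse than a failed join.
    """
    s = str(name).strip()
    if s[:3].lower() == "bxd":
        s = "BXD" + s[3:]
    return s


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise LoadError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes × strains expression table.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and strain names as
        columns.  All values must be finite numbers.
    scale
        Whether the values are raw log2 intensities or already on the
        modified Z scale (per-array mean 8, SD 2).
    """

    data: pd.DataFrame
    scale: Scale = Scale.RAW_LOG2

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        df = self.data
        df.index = pd.Index([str(g).strip() for g in df.index], name="gene")
        df.columns = pd.Index(
            [normalize_strain_name(c) for c in df.columns], name="strain"
        )
        _check_unique(list(df.index), "gene id")
        _check_unique(list(df.columns), "strain")
        values = df.to_numpy(dtype=float)  # raises on non-numeric cells
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise LoadError(
                f"non-finite expression value for gene {df.index[bad[0]]!r}, "
                f"strain {df.columns[bad[1]]!r}"
            )
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_strains(self) -> int:
        return self.data.shape[1]

    def restrict(
        self,
        genes: Sequence[str] | None = None,
        strains: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Subset to the given genes and/or strains, preserving the given order.

        Raises
        ------
        KeyError
            If any requested gene or strain is absent, listing the missing ids.
        """
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"genes absent from expression matrix: {missing}")
            df = df.loc[list(genes)]
        if strains is not None:
            strains = [normalize_strain_name(s) for s in strains]
            missing = [s for s in strains if s not in df.columns]
            if missing:
                raise KeyError(f"strains absent from expression matrix: {missing}")
            df = df[list(strains)]
        return ExpressionMatrix(df.copy(), self.scale)


_SEXES = {"M", "F", "unknown"}

_ABR_COLUMNS = [
    "strain",
    "individual",
    "sex",
    "age_months",
    "frequency_khz",
    "threshold_db",
]


@dataclass
class AbrRecordTable:
    """Per-individual, per-frequency ABR thresholds.

    One row per mouse × stimulus frequency.  Thresholds are dB SPL in
    [0, 120]; frequencies are restricted to the tested set {8, 16, 32} kHz.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing_cols = [c for c in _ABR_COLUMNS if c not in df.columns]
        if missing_cols:
            raise LoadError(f"ABR table missing columns: {missing_cols}")
        df = df[_ABR_COLUMNS]
        df["strain"] = df["strain"].map(normalize_strain_name)
        df["individual"] = df["individual"].astype(str).str.strip()
        df["sex"] = df["sex"].astype(str).str.strip()
        for i, sex in enumerate(df["sex"]):
            if sex not in _SEXES:
                raise LoadError(f"row {i}: sex {sex!r} not in {sorted(_SEXES)}")
        for col in ("age_months", "frequency_khz", "threshold_db"):
            try:
                df[col] = df[col].astype(float)
            except (TypeError, ValueError) as exc:
                raise LoadError(f"non-numeric value in column {col!r}: {exc}") from exc
        for i, row in enumerate(df.itertuples(index=False)):
            if row.frequency_khz not in VALID_FREQUENCIES_KHZ:
                raise LoadError(
                    f"row {i}: frequency {row.frequency_khz} kHz not in "
                    f"{VALID_FREQUENCIES_KHZ}"
                )
            lo, hi = THRESHOLD_RANGE_DB
            if not lo <= row.threshold_db <= hi:
                raise LoadError(
                    f"row {i}: threshold {row.threshold_db} dB SPL outside "
                    f"[{lo:g}, {hi:g}]"
                )
            if row.age_months < 0:
                raise LoadError(f"row {i}: negative age {row.age_months}")
        self.records = df.reset_index(drop=True)

    @property
    def strains(self) -> list[str]:
        return sorted(self.records["strain"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class StrainTraitVector:
    """One trait value per strain, with the number of individuals behind it."""

    table: pd.DataFrame  # index strain, columns trait_value, n_individuals

    def __post_init__(self) -> None:
        df = self.table.copy()
        df.index = pd.Index(
            [normalize_strain_name(s) for s in df.index], name="strain"
        )
        _check_unique(list(df.index), "strain")
        if not {"trait_value", "n_individuals"} <= set(df.columns):
            raise LoadError(
                "trait table needs columns 'trait_value' and 'n_individuals'"
            )
        df["trait_value"] = df["trait_value"].astype(float)
        df["n_individuals"] = df["n_individuals"].astype(int)
        if (df["n_individuals"] < 1).any():
            bad = df.index[df["n_individuals"] < 1][0]
            raise LoadError(f"strain {bad!r} has n_individuals < 1")
        self.table = df

    @property
    def strains(self) -> list[str]:
        return list(self.table.index)

    @property
    def values(self) -> pd.Series:
        return self.table["trait_value"]

    def restrict(self, strains: Sequence[str]) -> "StrainTraitVector":
        strains = [normalize_strain_name(s) for s in strains]
        missing = [s for s in strains if s not in self.table.index]
        if missing:
            raise KeyError(f"strains absent from trait vector: {missing}")
        return StrainTraitVector(self.table.loc[list(strains)].copy())

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise LoadError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GO/KEGG-style annotation)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene set name")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class PhenotypeTable:
    """Published phenotypes × strains, with missing entries allowed (NaN)."""

    data: pd.DataFrame  # index phenotype id, columns strains
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = pd.Index([str(p).strip() for p in df.index], name="phenotype")
        df.columns = pd.Index(
            [normalize_strain_name(c) for c in df.columns], name="strain"
        )
        _check_unique(list(df.index), "phenotype id")
        _check_unique(list(df.columns), "strain")
        df = df.astype(float)
        all_missing = df.index[df.isna().all(axis=1)]
        if len(all_missing):
            raise LoadError(
                f"phenotype {all_missing[0]!r} has no non-missing values"
            )
        self.data = df
        self.descriptions = {
            str(k): str(v) for k, v in self.descriptions.items()
        }

    @property
    def phenotype_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class SyntheticTruth:
    """Planted ground truth for a simulated panel (recovery testing only)."""

    associated_gene_ids: tuple[str, ...]
    target_r: float
    hub_gene_id: str | None
    module_gene_ids: tuple[str, ...]
    seed: int
    censoring_db: float

    def __post_init__(self) -> None:
        self.associated_gene_ids = tuple(self.associated_gene_ids)
        self.module_gene_ids = tuple(self.module_gene_ids)
        if self.hub_gene_id is not None and self.module_gene_ids:
            if self.hub_gene_id not in self.module_gene_ids:
                raise ValueError("hub gene must be a module member")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "associated_gene_ids": list(self.associated_gene_ids),
                    "target_r": self.target_r,
                    "hub_gene_id": self.hub_gene_id,
                    "module_gene_ids": list(self.module_gene_ids),
                    "seed": self.seed,
                    "censoring_db": self.censoring_db,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            associated_gene_ids=tuple(d["associated_gene_ids"]),
            target_r=d["target_r"],
            hub_gene_id=d["hub_gene_id"],
            module_gene_ids=tuple(d["module_gene_ids"]),
            seed=d["seed"],
            censoring_db=d["censoring_db"],
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_id_table(path: str | Path, what: str, allow_missing: bool) -> pd.DataFrame:
    """Read a TSV with a header row and the row id in the first column."""
    path = Path(path)
    na_values = ["NA", ""] if allow_missing else []
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=na_values,
            keep_default_na=False,
            dtype=str,
            encoding="utf-8",
        )
    except Exception as exc:  # malformed header / unreadable file
        raise LoadError(f"cannot read {what} table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise LoadError(f"{what} table {path} has no data columns (malformed header?)")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        raw = df[col]
        empty = raw.isna() | (raw.astype(str).str.strip() == "")
        if not allow_missing and empty.any():
            row = df.index[empty][0]
            raise LoadError(
                f"missing value in {what} table {path}: row {row!r}, column {col!r}"
            )
        converted = pd.to_numeric(df[col], errors="coerce")
        # numeric coercion must only fail where the cell was genuinely missing
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise LoadError(
                f"non-numeric cell in {what} table {path}: "
                f"row {row!r}, column {col!r} = {df.loc[row, col]!r}"
            )
        if not allow_missing and converted.isna().any():
            row = df.index[converted.isna()][0]
            raise LoadError(
                f"missing value in {what} table {path}: row {row!r}, column {col!r}"
            )
        out[col] = converted
    return out


def read_expression(path: str | Path, scale: Scale = Scale.RAW_LOG2) -> ExpressionMatrix:
    """Load a genes × strains expression TSV.

    The first column holds gene identifiers (treated as opaque strings), the
    header row holds strain names.  Missing or non-numeric cells and duplicate
    identifiers are load errors.
    """
    return ExpressionMatrix(_read_id_table(path, "expression", allow_missing=False), scale)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene")


def read_abr_records(path: str | Path) -> AbrRecordTable:
    """Load per-individual ABR threshold records from a TSV file."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    except Exception as exc:
        raise LoadError(f"cannot read ABR table {path}: {exc}") from exc
    return AbrRecordTable(df)


def write_abr_records(records: AbrRecordTable, path: str | Path) -> None:
    records.records.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Load a GMT gene-set file (name TAB description TAB member...).

    Duplicate member tokens within one line are deduplicated; duplicate set
    names across lines are an error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise LoadError(
                f"{path}: line {lineno} has {len(fields)} fields; GMT needs "
                "name, description and at least one member"
            )
        name, description, *members = fields
        members = [m.strip() for m in members if m.strip()]
        if not members:
            raise LoadError(f"{path}: line {lineno} ({name!r}) has no members")
        sets.append(GeneSet(name, description, frozenset(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([s.name, s.description, *sorted(s.members)]) for s in collection
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_phenotypes(path: str | Path, descriptions: Mapping[str, str] | None = None) -> PhenotypeTable:
    """Load a phenotypes × strains TSV; empty cells and ``NA`` are missing."""
    df = _read_id_table(path, "phenotype", allow_missing=True)
    return PhenotypeTable(df, dict(descriptions or {}))


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="phenotype", na_rep="NA")


def read_trait(path: str | Path) -> StrainTraitVector:
    """Load a per-strain trait TSV with columns strain, trait_value, n_individuals."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    except Exception as exc:
        raise LoadError(f"cannot read trait table {path}: {exc}") from exc
    return StrainTraitVector(df)


def write_trait(trait: StrainTraitVector, path: str | Path) -> None:
    trait.table.to_csv(path, sep="\t", index_label="strain")
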