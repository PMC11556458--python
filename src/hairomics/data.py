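"""Core data model and delimited-text I/O.

The whole pipeline operates on two tables:

* a **spectral-count matrix** — proteins as rows, subjects as columns,
  non-negative integer peptide-spectrum-match (PSM) counts per cell; and
* a **subject metadata table** — family membership, mother/child role,
  age in months, sex, and whether a child is biologically related to an
  enrolled mother.

Absence of a protein in a subject is encoded as a count of 0, never as a
missing value, so presence/absence (Boolean) profiles are always
recoverable.  Files are tab- or comma-delimited UTF-8 text; the delimiter
is sniffed from the header line with tab preferred.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "SpectralCountMatrix",
    "SubjectMetadata",
    "AnalysisConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_metadata",
    "write_metadata",
    "read_structural_list",
    "column_summaries",
    "load_demographics",
]

ROLES = ("mother", "child")
SEXES = ("F", "M")

METADATA_COLUMNS = ("family_id", "role", "age_months", "sex", "related")


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


# ---------------------------------------------------------------------------
# Spectral-count matrix
# ---------------------------------------------------------------------------

@dataclass
class SpectralCountMatrix:
    """Protein x subject matrix of non-negative integer spectral counts.

    Parameters
    ----------
    counts
        DataFrame indexed by protein id with one column per subject.
    structural
        Boolean Series aligned to the protein index flagging structural
        hair-shaft proteins (keratins and keratin-associated proteins),
        which most analyses exclude as contaminants.
    """

    counts: pd.DataFrame
    structural: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.structural is None:
            self.structural = pd.Series(False, index=self.counts.index)
        self.structural = self.structural.reindex(self.counts.index, fill_value=False).astype(bool)
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dupes}")
        if self.counts.columns.duplicated().any():
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate subject ids: {dupes}")
        values = self.counts.to_numpy()
        bad = ~np.isfinite(values) | (values < 0) | (np.mod(values, 1) != 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"count for protein {self.counts.index[i]!r}, subject "
                f"{self.counts.columns[j]!r} is {values[i, j]!r}: counts must be "
                "non-negative integers"
            )
        if self.counts.to_numpy().dtype.kind != "i":
            self.counts = self.counts.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_proteins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[1]

    def subset_proteins(self, protein_ids: Iterable[str]) -> "SpectralCountMatrix":
        ids = list(protein_ids)
        return SpectralCountMatrix(self.counts.loc[ids], self.structural.loc[ids])

    def subset_subjects(self, subject_ids: Iterable[str]) -> "SpectralCountMatrix":
        return SpectralCountMatrix(self.counts[list(subject_ids)], self.structural)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.counts.rename_axis("protein_id").to_csv(path, sep=sep)


def read_count_matrix(path: str | Path, structural_list: str | Path | None = None) -> SpectralCountMatrix:
    """Read a delimited protein x subject count table.

    First column holds protein ids, remaining columns one subject each.
    Proteins named in ``structural_list`` (one id per line) are flagged
    structural.  Non-integer or negative cells raise :class:`FormatError`
    naming the offending row and column.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, encoding="utf-8")
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric count {raw.iat[i, j]!r} for protein {raw.index[i]!r}, "
            f"subject {raw.columns[j]!r}"
        )
    structural = None
    if structural_list is not None:
        names = read_structural_list(structural_list)
        structural = pd.Series(numeric.index.isin(names), index=numeric.index)
    return SpectralCountMatrix(numeric, structural)


def write_count_matrix(matrix: SpectralCountMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.write(path, sep=sep)


def read_structural_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line list of structural proteins."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def column_summaries(matrix: SpectralCountMatrix) -> pd.DataFrame:
    """Per-subject totals: summed PSMs and number of proteins observed.

    Returns a DataFrame indexed by subject id with integer columns
    ``total_psms`` (column sum) and ``n_proteins`` (count of rows with a
    non-zero entry).  These are the two per-subject quantities the cohort
    demographics table prints.
    """
    totals = matrix.counts.sum(axis=0)
    n_proteins = (matrix.counts > 0).sum(axis=0)
    return pd.DataFrame({"total_psms": totals, "n_proteins": n_proteins}).rename_axis("subject_id")


# ---------------------------------------------------------------------------
# Subject metadata
# ---------------------------------------------------------------------------

class SubjectMetadata:
    """Validated per-subject annotations driving every grouped analysis.

    Wraps a DataFrame indexed by ``subject_id`` with columns
    ``family_id``, ``role`` ('mother'/'child'), ``age_months``, ``sex``
    ('F'/'M') and ``related`` (child biologically related to an enrolled
    mother).  Extra columns are preserved untouched.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if table.index.name != "subject_id":
            if "subject_id" in table.columns:
                table = table.set_index("subject_id")
            else:
                table = table.rename_axis("subject_id")
        missing = [c for c in METADATA_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        table.index = table.index.astype(str)
        table["related"] = table["related"].map(_to_bool)
        table["age_months"] = pd.to_numeric(table["age_months"])
        self.table = table
        self.validate()

    def validate(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise FormatError(f"duplicate subject ids: {t.index[t.index.duplicated()].tolist()}")
        bad_roles = sorted(set(t["role"]) - set(ROLES))
        if bad_roles:
            raise FormatError(f"unknown role(s) {bad_roles}; expected one of {ROLES}")
        bad_sex = sorted(set(t["sex"]) - set(SEXES))
        if bad_sex:
            raise FormatError(f"unknown sex value(s) {bad_sex}; expected one of {SEXES}")
        if (t["age_months"] < 0).any():
            raise FormatError("negative age_months")
        mothers = t[t["role"] == "mother"]
        counts = mothers.groupby("family_id").size()
        multi = counts[counts > 1]
        if len(multi):
            raise FormatError(f"families with more than one mother: {multi.index.tolist()}")
        # sanity check, not an error: a mother should be older than her children
        for fam, mother_age in mothers.set_index("family_id")["age_months"].items():
            kids = t[(t["family_id"] == fam) & (t["role"] == "child")]
            if (kids["age_months"] >= mother_age).any():
                warnings.warn(
                    f"family {fam}: a child is as old as or older than the mother",
                    stacklevel=2,
                )

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def mothers(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "mother"])

    @property
    def children(self) -> list[str]:
        return list(self.table.index[self.table["role"] == "child"])

    @property
    def family_ids(self) -> list[str]:
        return list(pd.unique(self.table["family_id"]))

    def families_with_mother(self) -> list[str]:
        return list(pd.unique(self.table.loc[self.table["role"] == "mother", "family_id"]))

    def mother_of(self, family_id: str) -> str:
        sel = self.table[(self.table["family_id"] == family_id) & (self.table["role"] == "mother")]
        if sel.empty:
            raise KeyError(f"family {family_id} has no mother")
        return sel.index[0]

    def children_of(self, family_id: str) -> list[str]:
        sel = self.table[(self.table["family_id"] == family_id) & (self.table["role"] == "child")]
        return list(sel.index)

    def subset(self, subject_ids: Iterable[str]) -> "SubjectMetadata":
        return SubjectMetadata(self.table.loc[list(subject_ids)])

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep)


def _to_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, np.integer, float)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "t", "yes", "1"}:
        return True
    if s in {"false", "f", "no", "0"}:
        return False
    raise FormatError(f"cannot interpret {value!r} as boolean")


def read_metadata(path: str | Path) -> SubjectMetadata:
    """Read a subject metadata table; empty file yields an empty collection."""
    path = Path(path)
    try:
        sep = _sniff_sep(path)
        table = pd.read_csv(path, sep=sep, encoding="utf-8")
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=("subject_id",) + METADATA_COLUMNS)
    if table.empty:
        warnings.warn(f"metadata file {path} contains no subjects", stacklevel=2)
        table = pd.DataFrame(columns=("subject_id",) + METADATA_COLUMNS)
    return SubjectMetadata(table)


def write_metadata(metadata: SubjectMetadata, path: str | Path, sep: str = "\t") -> None:
    metadata.write(path, sep=sep)


def load_demographics() -> tuple[SubjectMetadata, pd.DataFrame]:
    """Load the packaged study-cohort demographics table.

    The fixture records the 40 enrolled subjects — 8 mothers each with two
    biological children, plus 16 unrelated children — with age, sex,
    race/ethnicity, and the two per-subject hair-proteome summaries
    (number of proteins observed and total PSMs).

    Returns
    -------
    metadata
        :class:`SubjectMetadata` for the 40 subjects.
    summaries
        DataFrame indexed by subject id with columns ``n_proteins`` and
        ``total_psms``.  These printed totals are derived outputs of the
        upstream search pipeline, not inputs to any computation here.
    """
    ref = resources.files("hairomics") / "resources" / "cohort_demographics.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    meta = SubjectMetadata(table)
    summaries = meta.table[["n_proteins", "total_psms"]].astype(int)
    return meta, summaries


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable knobs of the analysis pipeline with study defaults.

    ``min_spectral_count`` is the protein inclusion threshold (a protein
    must reach it in at least one subject); ``n_pcs_for_tls`` and
    ``top_fraction`` govern driver selection from principal-component
    loadings; the permutation and cross-validation sizes follow the
    study design (5000 family permutations, 1000 embedding permutations,
    10-fold CV repeated 100 times).
    """

    min_spectral_count: int = 3
    exclusive_threshold: bool = False
    exclude_structural: bool = True
    n_pcs_for_tls: int = 5
    top_fraction: float = 0.05
    n_permutations: int = 5000
    n_tsne_permutations: int = 1000
    tsne_max_iter: int = 1000
    cv_folds: int = 10
    cv_repeats: int = 100
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        positive = {
            "min_spectral_count": self.min_spectral_count,
            "n_pcs_for_tls": self.n_pcs_for_tls,
            "n_permutations": self.n_permutations,
            "n_tsne_permutations": self.n_tsne_permutations,
            "tsne_max_iter": self.tsne_max_iter,
            "cv_folds": self.cv_folds,
            "cv_repeats": self.cv_repeats,
        }
        for name, value in positive.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if not (0 < self.top_fraction < 1):
            raise ValueError(f"top_fraction must lie in (0, 1), got {self.top_fraction}")
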