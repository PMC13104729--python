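"""Readers/writers, sample design handling, inter-sample normalization and
complete-case filtering.

All tables are UTF-8 CSV/TSV (dialect chosen by file extension); missing
values are empty cells, never zero — a zero is a measured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

ISOTOPOMER_COLUMNS = (
    "peptide_id",
    "sequence",
    "protein_accession",
    "sample_id",
    "time_h",
    "m0",
    "m1",
)
DESIGN_COLUMNS = ("sample_id", "condition", "replicate", "time_h", "labeled")

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _sep(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing required column(s): {missing}")


def read_design(path) -> pd.DataFrame:
    """Read and validate the sample design table.

    Enforces unique sample ids, a unique (condition, replicate, time_h,
    labeled) key, and an equal replicate count across conditions among the
    labeled samples.
    """
    df = pd.read_csv(path, sep=_sep(path))
    _require_columns(df, DESIGN_COLUMNS, "design table")
    df = df.loc[:, list(DESIGN_COLUMNS)].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    df["time_h"] = df["time_h"].astype(float)

    def to_bool(v):
        s = str(v).strip().lower()
        if s in _TRUTHY:
            return True
        if s in _FALSY:
            return False
        raise SchemaError(f"design column 'labeled' has non-boolean value {v!r}")

    df["labeled"] = df["labeled"].map(to_bool)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"duplicate sample_id in design: {dup!r}")
    key = df[["condition", "replicate", "time_h", "labeled"]]
    if key.duplicated().any():
        raise SchemaError("design (condition, replicate, time_h, labeled) key not unique")
    if (df["replicate"] < 1).any():
        raise SchemaError("replicate numbers must be >= 1")
    labeled = df[df["labeled"]]
    counts = labeled.groupby("condition")["replicate"].nunique()
    if counts.nunique() > 1:
        raise SchemaError(
            f"conditions have unequal replicate counts: {counts.to_dict()}"
        )
    return df


def read_isotopomer_table(path) -> pd.DataFrame:
    """Read the peptide mass-isotopomer table, validating the schema.

    Row numbers (1-based, excluding the header) are preserved in the index
    so downstream errors can point back at the file.
    """
    df = pd.read_csv(path, sep=_sep(path))
    _require_columns(df, ISOTOPOMER_COLUMNS, "isotopomer table")
    df = df.loc[:, list(ISOTOPOMER_COLUMNS)].copy()
    df.index = pd.RangeIndex(1, len(df) + 1, name="row")
    for col in ("peptide_id", "sequence", "protein_accession", "sample_id"):
        df[col] = df[col].astype(str)
    for col in ("time_h", "m0", "m1"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise SchemaError(
                f"isotopomer table row {row}: non-numeric value in column {col!r}"
            )
        df[col] = coerced.astype(float)
    if (df[["m0", "m1"]] < 0).any().any():
        raise SchemaError("isotopomer intensities must be non-negative")
    return df


def write_isotopomer_table(df: pd.DataFrame, path) -> None:
    df.loc[:, list(ISOTOPOMER_COLUMNS)].to_csv(path, sep=_sep(path), index=False)


@dataclass
class AbundanceMatrix:
    """Protein × sample abundance matrix (fmol/μg) with design metadata.

    ``values`` is a DataFrame indexed by protein accession with one column
    per sample_id; ``descriptions`` carries the free-text protein names used
    by the ribosome classifier.
    """

    values: pd.DataFrame
    descriptions: pd.Series | None = None
    normalized: bool = False
    reference_sample: str | None = None
    scaling_factors: pd.Series | None = None

    def __post_init__(self):
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise SchemaError("abundance values must be non-negative")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def read_abundance_table(path, design: pd.DataFrame) -> AbundanceMatrix:
    """Read a wide protein-abundance table.

    Expected columns: ``protein_accession``, optional ``description``, then
    one column per sample.  Every sample column must appear in the design;
    unknown columns are an error rather than silently dropped.
    """
    df = pd.read_csv(path, sep=_sep(path))
    _require_columns(df, ["protein_accession"], "abundance table")
    df["protein_accession"] = df["protein_accession"].astype(str)
    if df["protein_accession"].duplicated().any():
        dup = df.loc[df["protein_accession"].duplicated(), "protein_accession"].iloc[0]
        raise SchemaError(f"duplicate protein accession: {dup!r}")
    df = df.set_index("protein_accession")
    descriptions = None
    if "description" in df.columns:
        descriptions = df.pop("description").astype(str)
    known = set(design["sample_id"].astype(str))
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"abundance table has sample(s) not in design: {unknown}")
    values = df.apply(pd.to_numeric, errors="coerce").astype(float)
    non_numeric = values.isna() & df.notna()
    if non_numeric.any().any():
        col = non_numeric.any()[non_numeric.any()].index[0]
        raise SchemaError(f"abundance table: non-numeric value in sample column {col!r}")
    return AbundanceMatrix(values=values, descriptions=descriptions)


def write_abundance_table(matrix: AbundanceMatrix, path) -> None:
    df = matrix.values.copy()
    if matrix.descriptions is not None:
        df.insert(0, "description", matrix.descriptions.reindex(df.index))
    df.index.name = "protein_accession"
    df.to_csv(path, sep=_sep(path))


def normalize_intersample(
    matrix: AbundanceMatrix, reference: str | None = None
) -> AbundanceMatrix:
    """Inter-sample ratio normalization of an abundance matrix.

    Each sample is scaled by a single factor so that the median protein-wise
    ratio of that sample to the reference equals 1.  The reference is the
    sample whose per-sample median log-abundance sits at the overall median
    of those medians (first column wins ties), emulating the inter-sample
    abundance-ratio normalization applied by label-free quantification
    software; it is an emulation on tables, not a bit-exact clone.

    Zeros and missing cells are excluded from both the reference choice and
    the ratio medians.  The returned matrix records the reference sample and
    per-sample factors; passing that reference back in reproduces factors of
    exactly 1 (idempotency).
    """
    if matrix.normalized and reference is None:
        raise ValueError("matrix already normalized")
    values = matrix.values
    if values.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    positive = values.where(values > 0)
    if reference is None:
        medians = np.log(positive).median(axis=0)
        target = medians.median()
        reference = (medians - target).abs().idxmin()
    elif reference not in values.columns:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    ref = positive[reference]
    factors = {}
    for col in values.columns:
        ratios = (positive[col] / ref).dropna()
        if ratios.empty:
            raise SchemaError(
                f"sample {col!r} shares no nonzero proteins with reference {reference!r}"
            )
        factors[col] = 1.0 / float(ratios.median())
    factors = pd.Series(factors, name="scaling_factor")
    return AbundanceMatrix(
        values=values * factors,
        descriptions=matrix.descriptions,
        normalized=True,
        reference_sample=reference,
        scaling_factors=factors,
    )


def filter_complete_cases(
    values: pd.DataFrame,
    design: pd.DataFrame | None = None,
    time_h: float | None = None,
) -> tuple[pd.DataFrame, int]:
    """Retain only rows quantified in every required cell.

    With a design, the required columns are the sample ids of every labeled
    (condition, replicate) cell — optionally restricted to one time point —
    and all of them must be present as columns.  Without a design, every
    column of ``values`` is required.  Returns the filtered frame and the
    retained-row count.
    """
    if design is not None:
        lab = design[design["labeled"]]
        if time_h is not None:
            lab = lab[np.isclose(lab["time_h"].astype(float), time_h)]
        required = list(lab["sample_id"].astype(str))
        missing = [s for s in required if s not in values.columns]
        if missing:
            raise SchemaError(f"value table missing design sample column(s): {missing}")
    else:
        required = list(values.columns)
    keep = values[required].notna().all(axis=1)
    filtered = values.loc[keep]
    return filtered, int(keep.sum())
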