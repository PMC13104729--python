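"""Deuterium-labeling kinetics: RIA, plateau RIA, k_deg and FSR.

During metabolic labeling with deuterium oxide, newly synthesised peptides
incorporate ²H at carbon-bound positions, shifting signal from the
monoisotopic (m0) into the first heavy (m1) mass isotopomer.  The relative
isotopomer abundance ``RIA = m1 / (m0 + m1)`` rises from its natural baseline
toward a plateau set by the peptide's number of exchangeable H–C bonds (N)
and the precursor-pool enrichment excess (DH_exp − DH_nat)::

    RIA_plateau = 1 - 1 / ( 1/(1 - RIA_t0) + N * (DH_exp - DH_nat) )

The first-order turnover rate constant is obtained from the fractional rise
of RIA over a two-point labeling window, adjusted for any change in protein
abundance P between the window endpoints::

    f     = (RIA_t1 - RIA_t0) / (RIA_plateau - RIA_t0)
    k_deg = -(1 / (t1 - t0)) * ln(1 - f * P_t1/P_t0)

The fractional synthesis rate is ``FSR = 100 * k_deg`` (%/h), and protein
FSR is the median FSR over the protein's unique peptides.

Scalar operations here accept numpy arrays as well; table-level drivers
(:func:`peptide_kinetics_table`, :func:`protein_fsr_table`) flag records
that fall outside the model's log domain instead of discarding them
silently.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import LabelingDomainError, SchemaError

__all__ = [
    "STANDARD_RESIDUES",
    "PrecursorEnrichment",
    "LabelingWindow",
    "MassIsotopomerRecord",
    "load_exchangeable_hydrogens",
    "count_exchangeable_hydrogens",
    "compute_ria",
    "compute_ria_plateau",
    "compute_kdeg",
    "compute_fsr",
    "protein_fsr",
    "peptide_kinetics_table",
    "protein_fsr_table",
]

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Natural deuterium:hydrogen abundance ratio (VSMOW).
NATURAL_DH = 1.5576e-4


@dataclass(frozen=True)
class PrecursorEnrichment:
    """D:H ratio of the biosynthetic precursor pool.

    ``dh_exp`` is the experimental enrichment (0.04 for 4% D2O media) and
    ``dh_nat`` the natural-environment ratio.
    """

    dh_exp: float = 0.04
    dh_nat: float = NATURAL_DH

    def __post_init__(self):
        if not (0.0 <= self.dh_nat <= self.dh_exp < 1.0):
            raise ValueError(
                f"require 0 <= dh_nat <= dh_exp < 1, got "
                f"dh_nat={self.dh_nat}, dh_exp={self.dh_exp}"
            )

    @property
    def excess(self) -> float:
        """Enrichment excess DH_exp − DH_nat driving the plateau shift."""
        return self.dh_exp - self.dh_nat


@dataclass(frozen=True)
class LabelingWindow:
    """Two-point labeling window, in hours since labeling start."""

    t0_h: float = 12.0
    t1_h: float = 36.0

    def __post_init__(self):
        if not self.t1_h > self.t0_h:
            raise ValueError(f"t1_h must exceed t0_h, got {self.t0_h}..{self.t1_h}")
        if self.t0_h < 0:
            raise ValueError("window start must be non-negative")

    @property
    def duration_h(self) -> float:
        return self.t1_h - self.t0_h


@dataclass
class MassIsotopomerRecord:
    """One peptide's m0/m1 intensities in one sample at one time point."""

    peptide_id: str
    sequence: str
    protein_accession: str
    sample_id: str
    time_h: float
    m0: float
    m1: float

    def __post_init__(self):
        if self.m0 < 0 or self.m1 < 0:
            raise ValueError("isotopomer intensities must be non-negative")
        if self.time_h < 0:
            raise ValueError("time_h must be non-negative")


def load_exchangeable_hydrogens(path=None) -> dict[str, float]:
    """Load the per-residue exchangeable H–C bond table.

    The shipped default (``data/exchangeable_hydrogens.csv``) carries the
    standard literature values for the number of carbon-bound hydrogens per
    residue that equilibrate with body water during biosynthesis.  The file
    is a plain two-column CSV (residue, n) and may be replaced wholesale.
    """
    if path is None:
        path = importlib.resources.files("proteoturn").joinpath(
            "data/exchangeable_hydrogens.csv"
        )
    df = pd.read_csv(path)
    if list(df.columns) != ["residue", "n"]:
        raise SchemaError(
            f"exchangeable-hydrogen table must have columns residue,n; got {list(df.columns)}"
        )
    table = {str(r).strip().upper(): float(n) for r, n in zip(df["residue"], df["n"])}
    missing = sorted(set(STANDARD_RESIDUES) - set(table))
    if missing:
        raise SchemaError(f"exchangeable-hydrogen table missing residues: {missing}")
    if any(v < 0 for v in table.values()):
        raise SchemaError("exchangeable-hydrogen counts must be non-negative")
    return table


def count_exchangeable_hydrogens(sequence: str, table: Mapping[str, float]) -> float:
    """Total number N of ²H-exchangeable H–C bonds in a peptide.

    N is the plain sum of per-residue values over the sequence.
    """
    if not sequence:
        raise ValueError("empty peptide")
    total = 0.0
    for code in sequence.upper():
        try:
            total += table[code]
        except KeyError:
            raise ValueError(f"unknown residue code: {code!r}") from None
    return total


def compute_ria(m0, m1):
    """Relative isotopomer abundance m1 / (m0 + m1).

    Accepts scalars or numpy arrays; raises on negative intensities or a
    zero m0+m1 sum.
    """
    m0 = np.asarray(m0, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    if np.any(m0 < 0) or np.any(m1 < 0):
        raise ValueError("isotopomer intensities must be non-negative")
    total = m0 + m1
    if np.any(total <= 0):
        raise ValueError("zero isotopomer signal")
    out = m1 / total
    return float(out) if out.ndim == 0 else out


def compute_ria_plateau(ria_t0, n, enrichment: PrecursorEnrichment):
    """Asymptotic RIA at full labeling.

    Collapses exactly to the baseline when ``n == 0`` or when the enrichment
    excess is zero; strictly below 1 otherwise.
    """
    ria_t0 = np.asarray(ria_t0, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(ria_t0 < 0) or np.any(ria_t0 >= 1):
        if np.any(ria_t0 == 1):
            raise ValueError("degenerate baseline")
        raise ValueError("ria_t0 must be in [0, 1)")
    if np.any(n < 0):
        raise ValueError("n must be non-negative")
    shift = n * enrichment.excess
    with np.errstate(divide="ignore"):
        out = 1.0 - 1.0 / (1.0 / (1.0 - ria_t0) + shift)
    # N = 0 or zero enrichment excess collapses to the baseline exactly.
    out = np.where(shift == 0, ria_t0, out)
    return float(out) if out.ndim == 0 else out


def compute_kdeg(
    ria_t0: float,
    ria_t1: float,
    ria_plateau: float,
    window: LabelingWindow,
    abundance_ratio: float = 1.0,
) -> float:
    """Abundance-adjusted degradation rate constant (h⁻¹), scalar form.

    Raises :class:`~proteoturn.errors.LabelingDomainError` (caught and
    flagged by the table driver) when the fractional rise is negative
    (``"RIA decreased"``) or when the log argument leaves (0, 1]
    (``"labeling at/above plateau"``).
    """
    if abundance_ratio <= 0:
        raise ValueError("abundance_ratio must be positive")
    headroom = ria_plateau - ria_t0
    if headroom <= 0:
        raise ValueError("no labeling headroom")
    f = (ria_t1 - ria_t0) / headroom
    if f < 0:
        raise LabelingDomainError("RIA decreased")
    fr = f * abundance_ratio
    if fr >= 1:
        raise LabelingDomainError("labeling at/above plateau")
    return -np.log1p(-fr) / window.duration_h


def compute_fsr(k_deg: float) -> float:
    """Fractional synthesis rate in %/h: 100 × k_deg."""
    if k_deg < 0:
        raise ValueError("k_deg must be non-negative")
    return 100.0 * k_deg


def protein_fsr(peptide_fsrs) -> tuple[float, int]:
    """Median FSR over a protein's unique peptides, with support count.

    The even-count convention is the mean of the two central values.
    """
    values = np.asarray(list(peptide_fsrs), dtype=float)
    if values.size == 0:
        raise ValueError("no valid peptides")
    return float(np.median(values)), int(values.size)


# ---------------------------------------------------------------------------
# Table-level drivers
# ---------------------------------------------------------------------------

_KINETICS_COLUMNS = [
    "peptide_id",
    "sequence",
    "protein_accession",
    "condition",
    "replicate",
    "n_exchangeable",
    "ria_t0",
    "ria_t1",
    "ria_plateau",
    "abundance_ratio",
    "abundance_adjusted",
    "ria_t0_source",
    "k_deg",
    "fsr_pct_per_h",
    "valid",
    "reason",
]


def _safe_ria(df: pd.DataFrame) -> pd.Series:
    total = df["m0"] + df["m1"]
    ok = (df["m0"] >= 0) & (df["m1"] >= 0) & (total > 0)
    ria = pd.Series(np.where(ok, df["m1"] / total.where(ok, 1.0), np.nan), index=df.index)
    return ria


def peptide_kinetics_table(
    isotopomers: pd.DataFrame,
    design: pd.DataFrame,
    abundance=None,
    *,
    enrichment: PrecursorEnrichment | None = None,
    window: LabelingWindow | None = None,
    hydrogen_table: Mapping[str, float] | None = None,
    ria_t0_mode: str = "control",
) -> pd.DataFrame:
    """Per-peptide kinetics for every (condition, replicate) cell.

    Parameters
    ----------
    isotopomers
        Long table with columns peptide_id, sequence, protein_accession,
        sample_id, time_h, m0, m1.
    design
        Sample design (sample_id, condition, replicate, time_h, labeled).
    abundance
        Optional :class:`~proteoturn.tables.AbundanceMatrix` (ideally
        inter-sample normalized).  Supplies the protein-level P_t1/P_t0
        adjustment; proteins without usable abundance fall back to a ratio
        of 1 and are flagged ``abundance_adjusted=False``.
    ria_t0_mode
        ``"control"`` takes each peptide's baseline RIA as its mean across
        unlabeled (H2O) samples, falling back per-cell to the first labeled
        time point when a peptide has no control measurement;
        ``"first-timepoint"`` always uses the labeled window-start sample of
        the same (condition, replicate).  The source actually used is
        recorded per record.
    """
    if enrichment is None:
        enrichment = PrecursorEnrichment()
    if window is None:
        window = LabelingWindow()
    if hydrogen_table is None:
        hydrogen_table = load_exchangeable_hydrogens()
    if ria_t0_mode not in ("control", "first-timepoint"):
        raise ValueError(f"unknown ria_t0_mode: {ria_t0_mode!r}")

    design = design.set_index("sample_id", drop=False)
    unknown = sorted(set(isotopomers["sample_id"]) - set(design.index))
    if unknown:
        raise SchemaError(f"isotopomer table references samples not in design: {unknown}")

    df = isotopomers.copy()
    df["condition"] = design["condition"].reindex(df["sample_id"]).to_numpy()
    df["replicate"] = design["replicate"].reindex(df["sample_id"]).to_numpy()
    df["labeled"] = design["labeled"].reindex(df["sample_id"]).to_numpy()
    df["time_h"] = design["time_h"].reindex(df["sample_id"]).to_numpy(dtype=float)
    df["ria"] = _safe_ria(df)

    seq_of = df.drop_duplicates("peptide_id").set_index("peptide_id")["sequence"]
    if df.groupby("peptide_id")["sequence"].nunique().gt(1).any():
        raise SchemaError("peptide_id maps to more than one sequence")

    n_of = {
        seq: count_exchangeable_hydrogens(seq, hydrogen_table)
        for seq in seq_of.unique()
    }

    labeled = df[df["labeled"].astype(bool)]
    t1_rows = labeled[np.isclose(labeled["time_h"], window.t1_h)]
    t0_rows = labeled[np.isclose(labeled["time_h"], window.t0_h)]
    # A peptide shared between proteins appears once per accession; the
    # record key is therefore (peptide, protein, condition, replicate).
    if t1_rows.duplicated(
        ["peptide_id", "protein_accession", "condition", "replicate"]
    ).any():
        raise SchemaError("duplicate window-end measurement for a peptide/cell")

    out = t1_rows[
        ["peptide_id", "protein_accession", "condition", "replicate"]
    ].copy()
    out["ria_t1"] = t1_rows["ria"].to_numpy()

    # Baseline RIA per the requested mode.
    t0_cell = t0_rows.set_index(["peptide_id", "condition", "replicate"])["ria"]
    t0_cell = t0_cell[~t0_cell.index.duplicated()]
    cell_index = pd.MultiIndex.from_frame(out[["peptide_id", "condition", "replicate"]])
    first_tp = t0_cell.reindex(cell_index).to_numpy()
    if ria_t0_mode == "control":
        ctrl = df[~df["labeled"].astype(bool)]
        ctrl_mean = ctrl.groupby("peptide_id")["ria"].mean()
        from_ctrl = ctrl_mean.reindex(out["peptide_id"]).to_numpy()
        out["ria_t0"] = np.where(np.isfinite(from_ctrl), from_ctrl, first_tp)
        out["ria_t0_source"] = np.where(
            np.isfinite(from_ctrl), "control", "first-timepoint"
        )
    else:
        out["ria_t0"] = first_tp
        out["ria_t0_source"] = "first-timepoint"

    out["sequence"] = seq_of.reindex(out["peptide_id"]).to_numpy()
    out["n_exchangeable"] = out["sequence"].map(n_of).to_numpy()

    # Abundance adjustment: protein-level P_t1/P_t0 per (condition, replicate).
    ratio = np.ones(len(out))
    adjusted = np.zeros(len(out), dtype=bool)
    if abundance is not None:
        lab = design[design["labeled"].astype(bool)]
        sample_of = {
            (row.condition, row.replicate, float(row.time_h)): row.sample_id
            for row in lab.itertuples()
        }
        values = abundance.values
        parts = []
        for cond, rep in out[["condition", "replicate"]].drop_duplicates().itertuples(
            index=False
        ):
            s0 = sample_of.get((cond, rep, window.t0_h))
            s1 = sample_of.get((cond, rep, window.t1_h))
            if s0 is None or s1 is None:
                continue
            p0 = values[s0]
            p1 = values[s1]
            r = p1 / p0
            r[~(np.isfinite(p0) & np.isfinite(p1) & (p0 > 0) & (p1 > 0))] = np.nan
            r.index = pd.MultiIndex.from_arrays(
                [values.index, [cond] * len(r), [rep] * len(r)]
            )
            parts.append(r)
        if parts:
            ratios = pd.concat(parts)
            looked = ratios.reindex(
                pd.MultiIndex.from_arrays(
                    [out["protein_accession"], out["condition"], out["replicate"]]
                )
            ).to_numpy(dtype=float)
            adjusted = np.isfinite(looked)
            ratio = np.where(adjusted, looked, 1.0)
    out["abundance_ratio"] = ratio
    out["abundance_adjusted"] = adjusted

    # Vectorized kinetics with validity flags.
    ria_t0 = out["ria_t0"].to_numpy(dtype=float)
    ria_t1 = out["ria_t1"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plateau = 1.0 - 1.0 / (
            1.0 / (1.0 - ria_t0) + out["n_exchangeable"].to_numpy() * enrichment.excess
        )
        headroom = plateau - ria_t0
        f = (ria_t1 - ria_t0) / headroom
        fr = f * ratio
        k = -np.log1p(-np.clip(fr, None, 1.0 - 1e-300)) / window.duration_h

    reason = np.full(len(out), "", dtype=object)
    bad_signal = ~np.isfinite(ria_t1) | ~np.isfinite(ria_t0)
    reason[bad_signal] = "zero isotopomer signal"
    no_headroom = ~bad_signal & ((headroom <= 0) | (ria_t0 >= 1))
    reason[no_headroom] = "no labeling headroom"
    decreased = ~bad_signal & ~no_headroom & (f < 0)
    reason[decreased] = "RIA decreased"
    at_plateau = ~bad_signal & ~no_headroom & ~decreased & (fr >= 1)
    reason[at_plateau] = "labeling at/above plateau"
    valid = reason == ""

    out["ria_plateau"] = plateau
    out["k_deg"] = np.where(valid, k, np.nan)
    out["fsr_pct_per_h"] = np.where(valid, 100.0 * k, np.nan)
    out["valid"] = valid
    out["reason"] = reason
    return out[_KINETICS_COLUMNS].reset_index(drop=True)


def protein_fsr_table(kinetics: pd.DataFrame) -> pd.DataFrame:
    """Roll peptide FSR up to protein level.

    Only valid records of peptides that map to a single protein accession
    contribute; the protein value is the median FSR with the number of
    distinct supporting peptides.
    """
    per_pep = kinetics.groupby("peptide_id")["protein_accession"].nunique()
    shared = set(per_pep[per_pep > 1].index)
    rows = kinetics[kinetics["valid"] & ~kinetics["peptide_id"].isin(shared)]
    if rows.empty:
        raise ValueError("no valid peptides")
    grouped = (
        rows.groupby(["protein_accession", "condition", "replicate"])
        .agg(
            median_fsr_pct_per_h=("fsr_pct_per_h", "median"),
            n_peptides=("peptide_id", "nunique"),
        )
        .reset_index()
    )
    return grouped


def fsr_wide(protein_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long protein-FSR table to proteins × (condition, replicate)."""
    wide = protein_table.pivot_table(
        index="protein_accession",
        columns=["condition", "replicate"],
        values="median_fsr_pct_per_h",
        aggfunc="first",
    )
    return wide.sort_index()
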