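"""Ribosomal-protein extraction, subunit classification and per-replicate
subunit summaries (median FSR, total abundance) with treatment contrasts.

Classification is a pure function of the free-text protein description:
candidates contain the substring "ribosom" (case-insensitive, so both
"ribosome" and "ribosomal" match) and are assigned to the cytosolic
(40S/60S) or mitochondrial (28S/39S) subunit by the corresponding token.
Candidates without a subunit token (e.g. biogenesis factors) stay
unclassified and are excluded from subunit summaries.
"""

from __future__ import annotations

import re
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from . import stats
from .errors import StatsPreconditionError
from .tables import AbundanceMatrix

CYTOSOLIC_SUBUNITS = ("40S", "60S")
MITOCHONDRIAL_SUBUNITS = ("28S", "39S")
SUBUNITS = CYTOSOLIC_SUBUNITS + MITOCHONDRIAL_SUBUNITS

_CANDIDATE_RE = re.compile(r"ribosom", re.IGNORECASE)
_SUBUNIT_RE = re.compile(r"(?<![0-9A-Za-z])(40S|60S|28S|39S)(?![0-9A-Za-z])", re.IGNORECASE)


def classify_ribosomal(descriptions: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Annotate proteins as ribosomal-subunit members from their descriptions.

    Returns one row per input protein with columns ``description``,
    ``is_candidate`` (matched "ribosom"), ``compartment``
    (cytosolic/mitochondrial/unclassified) and ``subunit``
    (40S/60S/28S/39S/unclassified).
    """
    if isinstance(descriptions, pd.Series):
        items = descriptions.items()
    else:
        items = descriptions.items()
    rows = []
    for accession, desc in items:
        desc = "" if desc is None else str(desc)
        candidate = bool(_CANDIDATE_RE.search(desc))
        subunit = "unclassified"
        compartment = "unclassified"
        if candidate:
            m = _SUBUNIT_RE.search(desc)
            if m:
                subunit = m.group(1).upper()
                compartment = (
                    "cytosolic" if subunit in CYTOSOLIC_SUBUNITS else "mitochondrial"
                )
        rows.append((accession, desc, candidate, compartment, subunit))
    return pd.DataFrame(
        rows,
        columns=["protein_accession", "description", "is_candidate", "compartment", "subunit"],
    ).set_index("protein_accession")


def subunit_summaries(
    annotations: pd.DataFrame,
    protein_fsr: pd.DataFrame,
    abundance: AbundanceMatrix,
    design: pd.DataFrame,
    *,
    abundance_time_h: float = 36.0,
    abundance_stat: str = "sum",
    control: str = "VC",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(subunit, condition, replicate) summaries and percent changes.

    For each classified subunit: the median FSR over member proteins and the
    total (sum; median optional) member abundance at the end-of-window time
    point, per replicate.  Condition-level percent change versus the control
    is computed from replicate means as ``100 * (mean_T - mean_VC)/mean_VC``.
    Subunits without any member present in the data are omitted with a
    warning.
    """
    if abundance_stat not in ("sum", "median"):
        raise ValueError("abundance_stat must be 'sum' or 'median'")
    members = {
        su: set(annotations.index[annotations["subunit"] == su]) for su in SUBUNITS
    }
    lab = design[design["labeled"]]
    t1 = lab[np.isclose(lab["time_h"].astype(float), abundance_time_h)]
    sample_of = {(r.condition, r.replicate): r.sample_id for r in t1.itertuples()}
    cells = sorted(
        {(r.condition, r.replicate) for r in lab.itertuples()},
        key=lambda cr: (cr[0], cr[1]),
    )
    agg = np.sum if abundance_stat == "sum" else np.median
    rows = []
    for su in SUBUNITS:
        present_fsr = protein_fsr[protein_fsr["protein_accession"].isin(members[su])]
        present_ab = abundance.values.index.intersection(members[su])
        if present_fsr.empty and len(present_ab) == 0:
            if members[su]:
                warnings.warn(f"subunit {su}: no members present in the data")
            continue
        for cond, rep in cells:
            cell = present_fsr[
                (present_fsr["condition"] == cond) & (present_fsr["replicate"] == rep)
            ]
            median_fsr = (
                float(cell["median_fsr_pct_per_h"].median()) if not cell.empty else np.nan
            )
            sample = sample_of.get((cond, rep))
            if sample is not None and len(present_ab):
                vals = abundance.values.loc[present_ab, sample].dropna()
                total = float(agg(vals.to_numpy())) if len(vals) else np.nan
            else:
                total = np.nan
            rows.append((su, cond, rep, median_fsr, total))
    summaries = pd.DataFrame(
        rows,
        columns=["subunit", "condition", "replicate", "median_fsr", "total_abundance"],
    )

    pct_rows = []
    for su, grp in summaries.groupby("subunit"):
        for metric in ("median_fsr", "total_abundance"):
            means = grp.groupby("condition")[metric].mean()
            if control not in means or not np.isfinite(means[control]) or means[control] == 0:
                continue
            for cond, mean_t in means.items():
                if cond == control or not np.isfinite(mean_t):
                    continue
                pct = 100.0 * (mean_t - means[control]) / means[control]
                pct_rows.append((su, cond, metric, pct))
    pct_change = pd.DataFrame(
        pct_rows, columns=["subunit", "condition", "metric", "pct_change_vs_vc"]
    )
    return summaries, pct_change


def subunit_contrasts(
    summaries: pd.DataFrame, *, control: str = "VC", alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA across conditions on replicate-level subunit summaries,
    with Tukey-adjusted pairwise p-values for each treatment versus control.

    The Tukey step is always computed but flagged ``gated`` when the omnibus
    p fails the significance gate.
    """
    rows = []
    for (su, metric), grp in _iter_subunit_metric(summaries):
        piv = grp.pivot_table(index="replicate", columns="condition", values=metric)
        piv = piv.dropna(axis=0)
        conditions = [c for c in piv.columns]
        if control not in conditions or len(conditions) < 2 or len(piv) < 2:
            continue
        groups = [piv[c].to_numpy(dtype=float) for c in conditions]
        try:
            F, p = stats.one_way_anova(groups)
        except StatsPreconditionError:
            continue
        tukey = stats.tukey_hsd(groups, labels=conditions)
        for t in tukey.itertuples():
            pair = {t.group_a, t.group_b}
            if control not in pair:
                continue
            treatment = (pair - {control}).pop()
            diff = (
                piv[treatment].mean() - piv[control].mean()
            )
            rows.append(
                (su, metric, treatment, F, p, float(t.p_adj), float(diff), p < alpha)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subunit",
            "metric",
            "treatment",
            "f_stat",
            "p_omnibus",
            "p_tukey",
            "mean_diff_vs_vc",
            "omnibus_significant",
        ],
    )


def _iter_subunit_metric(summaries: pd.DataFrame):
    for su in sorted(summaries["subunit"].unique()):
        grp = summaries[summaries["subunit"] == su]
        for metric in ("median_fsr", "total_abundance"):
            yield (su, metric), grp
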