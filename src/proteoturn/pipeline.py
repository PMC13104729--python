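"""End-to-end pipeline: read → normalize → kinetics → roll-up → filter →
statistics → ribosome summaries, with run manifests for exact reruns.

`run_fsr` covers the kinetics half (peptide RIA/plateau/k_deg/FSR, protein
median roll-up, complete-case filtering); `run_stats` the inferential half
(treatment-vs-control contrasts with Storey q-values, condition×time
interaction clustering, ribosomal subunit summaries/contrasts, and log2
fold-change correlations).  Every output directory carries a
``manifest.json`` with the tool version, configuration, input hashes and
stage counts, so an identical rerun produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, kinetics, ribosome, stats, tables
from .errors import SchemaError, StatsPreconditionError


@dataclass
class PipelineConfig:
    """Paths and tunables for one pipeline run; loadable from flat YAML."""

    isotopomer_path: str | None = None
    abundance_path: str | None = None
    design_path: str | None = None
    descriptions_path: str | None = None
    out_dir: str = "proteoturn_out"
    dh_exp: float = 0.04
    dh_nat: float = kinetics.NATURAL_DH
    t0_h: float = 12.0
    t1_h: float = 36.0
    ria_t0_mode: str = "control"
    control: str = "VC"
    alpha: float = 0.05
    cluster_k: int = 5
    subunit_abundance: str = "sum"
    hydrogen_table_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    @property
    def enrichment(self) -> kinetics.PrecursorEnrichment:
        return kinetics.PrecursorEnrichment(dh_exp=self.dh_exp, dh_nat=self.dh_nat)

    @property
    def window(self) -> kinetics.LabelingWindow:
        return kinetics.LabelingWindow(t0_h=self.t0_h, t1_h=self.t1_h)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path, what: str) -> Path:
    if path is None:
        raise SchemaError(f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"{what} not found: {p}")
    return p


def _write_manifest(outdir: Path, stage: str, config: PipelineConfig, inputs, counts):
    manifest = {
        "tool": "proteoturn",
        "version": __version__,
        "stage": stage,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {name: _sha256(p) for name, p in inputs.items()},
        "counts": counts,
    }
    with open(outdir / f"manifest_{stage}.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def run_fsr(config: PipelineConfig) -> dict:
    """Kinetics stage: peptide kinetics, protein FSR, complete-case filter."""
    iso_path = _require(config.isotopomer_path, "isotopomer table")
    design_path = _require(config.design_path, "design table")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    design = tables.read_design(design_path)
    isotopomers = tables.read_isotopomer_table(iso_path)
    inputs = {"isotopomers": iso_path, "design": design_path}

    abundance = None
    if config.abundance_path is not None:
        ab_path = _require(config.abundance_path, "abundance table")
        inputs["abundance"] = ab_path
        abundance = tables.read_abundance_table(ab_path, design)
        if abundance.values.shape[1] >= 2:
            abundance = tables.normalize_intersample(abundance)
        tables.write_abundance_table(abundance, outdir / "abundance_normalized.csv")

    hydrogen_table = kinetics.load_exchangeable_hydrogens(config.hydrogen_table_path)
    kin = kinetics.peptide_kinetics_table(
        isotopomers,
        design,
        abundance,
        enrichment=config.enrichment,
        window=config.window,
        hydrogen_table=hydrogen_table,
        ria_t0_mode=config.ria_t0_mode,
    )
    kin.to_csv(outdir / "peptide_kinetics.csv", index=False)

    protein = kinetics.protein_fsr_table(kin)
    protein.to_csv(outdir / "protein_fsr.csv", index=False)

    wide = kinetics.fsr_wide(protein)
    grid = [
        (c, r)
        for c in sorted(design.loc[design["labeled"], "condition"].unique())
        for r in sorted(design.loc[design["labeled"], "replicate"].unique())
    ]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(grid))
    filtered, n_complete = tables.filter_complete_cases(wide)
    long_filtered = (
        filtered.stack([0, 1], future_stack=True)
        .rename("median_fsr_pct_per_h")
        .reset_index()
    )
    long_filtered.columns = [
        "protein_accession",
        "condition",
        "replicate",
        "median_fsr_pct_per_h",
    ]
    long_filtered = long_filtered.merge(
        protein, on=["protein_accession", "condition", "replicate", "median_fsr_pct_per_h"],
        how="left",
    )
    long_filtered.to_csv(outdir / "protein_fsr_filtered.csv", index=False)

    counts = {
        "isotopomer_rows": int(len(isotopomers)),
        "peptides": int(kin["peptide_id"].nunique()),
        "peptide_records": int(len(kin)),
        "peptide_records_valid": int(kin["valid"].sum()),
        "proteins_quantified": int(protein["protein_accession"].nunique()),
        "proteins_complete_cases": int(n_complete),
    }
    manifest = _write_manifest(outdir, "fsr", config, inputs, counts)
    return {"counts": counts, "manifest": manifest, "out_dir": str(outdir)}


def _condition_groups(design: pd.DataFrame, time_h: float | None = None):
    lab = design[design["labeled"]]
    if time_h is not None:
        lab = lab[np.isclose(lab["time_h"].astype(float), time_h)]
    return {
        cond: list(grp.sort_values("replicate")["sample_id"])
        for cond, grp in lab.groupby("condition")
    }


def _contrast_frame(values: pd.DataFrame, groups: dict, treatment: str, control: str):
    """Per-protein one-way ANOVA of treatment vs control plus log2 FC."""
    t = values[groups[treatment]].to_numpy(dtype=float)
    c = values[groups[control]].to_numpy(dtype=float)
    F, p = stats.one_way_anova_matrix([t, c])
    mean_t = t.mean(axis=1)
    mean_c = c.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.where(
            (mean_t > 0) & (mean_c > 0), np.log2(mean_t / mean_c), np.nan
        )
    q = stats.storey_qvalues(np.clip(p, np.finfo(float).tiny, 1.0))
    return pd.DataFrame(
        {
            "protein_accession": values.index,
            "contrast": f"{treatment}-vs-{control}",
            "f_stat": F,
            "p_value": p,
            "q_value": q,
            "log2_fc": log2_fc,
            "direction": np.where(mean_t >= mean_c, "up", "down"),
        }
    )


def run_stats(config: PipelineConfig) -> dict:
    """Inferential stage; requires `run_fsr` outputs in the same out_dir."""
    outdir = Path(config.out_dir)
    fsr_path = _require(outdir / "protein_fsr_filtered.csv", "filtered protein-FSR table")
    design_path = _require(config.design_path, "design table")
    design = tables.read_design(design_path)
    control = config.control
    treatments = sorted(
        set(design.loc[design["labeled"], "condition"]) - {control}
    )
    inputs = {"protein_fsr_filtered": fsr_path, "design": design_path}
    counts: dict = {}

    fsr_long = pd.read_csv(fsr_path)
    fsr_wide_cells = fsr_long.pivot_table(
        index="protein_accession",
        columns=["condition", "replicate"],
        values="median_fsr_pct_per_h",
        aggfunc="first",
    ).sort_index()
    fsr_by_cond = {
        cond: fsr_wide_cells[cond] for cond in fsr_wide_cells.columns.levels[0]
    }
    counts["fsr_proteins"] = int(len(fsr_wide_cells))

    # Mixed (sample-level) FSR: median across proteins per condition/replicate.
    mixed = (
        fsr_long.groupby(["condition", "replicate"])["median_fsr_pct_per_h"]
        .median()
        .rename("mixed_fsr_pct_per_h")
        .reset_index()
    )
    mixed.to_csv(outdir / "mixed_fsr.csv", index=False)
    mixed_groups = [
        grp["mixed_fsr_pct_per_h"].to_numpy()
        for _, grp in mixed.groupby("condition")
    ]
    mixed_F, mixed_p = stats.one_way_anova(mixed_groups)
    pd.DataFrame(
        {"f_stat": [mixed_F], "p_value": [mixed_p], "n_conditions": [len(mixed_groups)]}
    ).to_csv(outdir / "mixed_fsr_anova.csv", index=False)

    # Per-protein FSR contrasts, one per treatment.
    fsr_groups = {
        cond: [(cond, r) for r in sorted(fsr_wide_cells[cond].columns)]
        for cond in fsr_by_cond
    }
    fsr_contrasts = []
    for treatment in treatments:
        cols = {
            treatment: fsr_groups[treatment],
            control: fsr_groups[control],
        }
        fsr_contrasts.append(
            _contrast_frame(fsr_wide_cells, cols, treatment, control)
        )
    fsr_contrasts = pd.concat(fsr_contrasts, ignore_index=True)
    fsr_contrasts.to_csv(outdir / "fsr_contrasts.csv", index=False)

    # Abundance analyses need the normalized matrix from the kinetics stage.
    ab_contrasts = None
    interaction = None
    clusters = None
    abundance = None
    ab_path = outdir / "abundance_normalized.csv"
    if ab_path.exists():
        inputs["abundance_normalized"] = ab_path
        abundance = tables.read_abundance_table(ab_path, design)
        abundance.normalized = True
        t0 = min(design.loc[design["labeled"], "time_h"])
        t1 = max(design.loc[design["labeled"], "time_h"])
        ab_complete, n_ab = tables.filter_complete_cases(abundance.values, design)
        counts["abundance_proteins_complete_cases"] = int(n_ab)

        groups_t1 = _condition_groups(design, time_h=t1)
        ab_contrasts = pd.concat(
            [
                _contrast_frame(ab_complete, groups_t1, treatment, control)
                for treatment in treatments
            ],
            ignore_index=True,
        )
        ab_contrasts.to_csv(outdir / "abundance_contrasts.csv", index=False)

        # Two-way condition × time ANOVA with interaction.
        conds = sorted(set(design.loc[design["labeled"], "condition"]))
        reps = sorted(set(design.loc[design["labeled"], "replicate"]))
        lab = design[design["labeled"]].set_index(["condition", "replicate", "time_h"])
        sample_grid = [
            [
                [lab.loc[(c, r, t), "sample_id"] for r in reps]
                for t in (t0, t1)
            ]
            for c in conds
        ]
        arr = np.stack(
            [
                np.stack(
                    [ab_complete[cols].to_numpy(dtype=float) for cols in by_time],
                    axis=1,
                )
                for by_time in sample_grid
            ],
            axis=1,
        )  # (n_proteins, a=conditions, b=times, r=replicates)
        res = stats.two_way_anova_matrix(arr)
        interaction = pd.DataFrame(
            {
                "protein_accession": ab_complete.index,
                "f_condition": res["f_a"],
                "p_condition": res["p_a"],
                "f_time": res["f_b"],
                "p_time": res["p_b"],
                "f_interaction": res["f_ab"],
                "p_interaction": res["p_ab"],
            }
        )
        interaction.to_csv(outdir / "interaction_anova.csv", index=False)
        sig = interaction[interaction["p_interaction"] < config.alpha]
        counts["interaction_significant"] = int(len(sig))

        if len(sig) >= config.cluster_k:
            cell_means = {}
            for ci, c in enumerate(conds):
                for ti, t in enumerate((t0, t1)):
                    cell_means[f"{c}_t{int(t)}h"] = arr[:, ci, ti, :].mean(axis=1)
            profiles = pd.DataFrame(cell_means, index=ab_complete.index).loc[
                sig["protein_accession"]
            ]
            clusters = stats.cluster_interaction_profiles(profiles, config.cluster_k)
            clusters.insert(
                0, "clustering", f"ward-euclidean-z(k={config.cluster_k})"
            )
            clusters.to_csv(outdir / "interaction_clusters.csv")
            counts["clusters"] = int(clusters["cluster_id"].nunique())
        else:
            counts["clusters"] = 0

    # Ribosome subunit profile.
    annotations = None
    if config.descriptions_path is not None or (
        abundance is not None and abundance.descriptions is not None
    ):
        if config.descriptions_path is not None:
            desc_path = _require(config.descriptions_path, "descriptions table")
            inputs["descriptions"] = desc_path
            desc_df = pd.read_csv(desc_path)
            for col in ("protein_accession", "description"):
                if col not in desc_df.columns:
                    raise SchemaError(f"descriptions table missing column {col!r}")
            descriptions = desc_df.set_index("protein_accession")["description"]
        else:
            descriptions = abundance.descriptions
        annotations = ribosome.classify_ribosomal(descriptions)
        annotations.to_csv(outdir / "ribosome_annotations.csv")
        if abundance is not None:
            summaries, pct = ribosome.subunit_summaries(
                annotations,
                fsr_long,
                abundance,
                design,
                abundance_time_h=float(max(design.loc[design["labeled"], "time_h"])),
                abundance_stat=config.subunit_abundance,
                control=control,
            )
            summaries.to_csv(outdir / "subunit_summaries.csv", index=False)
            pct.to_csv(outdir / "subunit_pct_change.csv", index=False)
            contrasts = ribosome.subunit_contrasts(
                summaries, control=control, alpha=config.alpha
            )
            contrasts.to_csv(outdir / "subunit_contrasts.csv", index=False)
            counts["ribosomal_candidates"] = int(annotations["is_candidate"].sum())

    # log2 fold-change correlations.
    corr_rows = []
    fc_fsr = {}
    for treatment in treatments:
        sub = fsr_contrasts[fsr_contrasts["contrast"] == f"{treatment}-vs-{control}"]
        fc_fsr[treatment] = sub.set_index("protein_accession")["log2_fc"]
    if ab_contrasts is not None:
        for treatment in treatments:
            sub = ab_contrasts[
                ab_contrasts["contrast"] == f"{treatment}-vs-{control}"
            ].set_index("protein_accession")["log2_fc"]
            try:
                res = stats.correlate_log2fc(fc_fsr[treatment], sub)
            except StatsPreconditionError:
                continue
            corr_rows.append(
                (f"FSR-vs-abundance ({treatment})", res.r, res.r_squared,
                 res.p_value, res.n, res.n_dropped)
            )
    if len(treatments) >= 2:
        a, b = treatments[0], treatments[1]
        try:
            res = stats.correlate_log2fc(fc_fsr[a], fc_fsr[b])
            corr_rows.append(
                (f"FSR {a}-vs-{b}", res.r, res.r_squared, res.p_value, res.n,
                 res.n_dropped)
            )
        except StatsPreconditionError:
            pass
    correlations = pd.DataFrame(
        corr_rows, columns=["comparison", "r", "r_squared", "p_value", "n", "n_dropped"]
    )
    correlations.to_csv(outdir / "correlations.csv", index=False)

    manifest = _write_manifest(outdir, "stats", config, inputs, counts)
    return {"counts": counts, "manifest": manifest, "out_dir": str(outdir)}
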