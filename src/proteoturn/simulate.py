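"""Ground-truth-known synthetic datasets with the statistical structure the
analysis assumes.

The generator emulates a deuterium-oxide labeling study in cultured
myotubes: three conditions (vehicle control plus two treatments) × three
biological replicates × two time points (12 and 36 h), with unlabeled
(H2O) control samples carrying the natural isotopic baseline.  Protein
turnover is first-order with a log-normal protein-to-protein spread around
a ~0.9 %/h median; a designated "ribosomal" subset responds to treatment
with a dedicated synthesis multiplier (~1.8×) and a modest abundance gain
at the end of the window, mirroring the effect sizes such studies report.

The forward model for labeling is the exact algebraic inverse of the
two-point rise-to-plateau estimator::

    RIA(t1) = RIA(t0) + (RIA_plateau - RIA(t0)) * (1 - e^(-k (t1-t0))) / ratio

where ``ratio`` is the realized (normalized) protein abundance ratio the
analysis itself will compute — so with zero intensity noise the pipeline
recovers every true k_deg exactly, and any discrepancy is an estimator
defect rather than model misspecification.

Randomness is split across independent seeded streams (structure,
abundance noise, intensity noise, guard resampling) so that re-running
with a different noise level preserves the proteome.  (SimConfig, seed) →
byte-identical output files.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics
from .errors import ProteoturnError
from .tables import AbundanceMatrix, normalize_intersample

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_TRYPTIC_END = "KR"


def _meanone_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults reproduce the labeling design the pipeline targets: 3
    conditions × 3 replicates × 12/36 h with 4% D2O enrichment, ~0.9 %/h
    baseline fractional synthesis with log-normal protein spread, a
    ribosomal subset whose synthesis responds ~1.8× to treatment (plus a
    ~17–18% end-of-window abundance gain), and 5% multiplicative intensity
    noise applied independently to the m0 and m1 channels.
    """

    conditions: tuple = ("VC", "IBU", "PEA")
    control: str = "VC"
    n_replicates: int = 3
    t0_h: float = 12.0
    t1_h: float = 36.0
    n_proteins: int = 300
    peptides_per_protein: tuple = (2, 6)
    baseline_fsr_median: float = 0.9          # %/h
    fsr_lognormal_sigma: float = 0.5          # ln-units, protein-to-protein
    ribosomal_fraction: float = 0.08
    fsr_multipliers: dict = field(default_factory=lambda: {"IBU": 1.0, "PEA": 1.0})
    ribosomal_fsr_multipliers: dict = field(
        default_factory=lambda: {"IBU": 1.8, "PEA": 1.8}
    )
    ribosomal_abundance_multipliers: dict = field(
        default_factory=lambda: {"IBU": 1.17, "PEA": 1.18}
    )
    abundance_baseline_range: tuple = (5.0, 200.0)   # fmol/ug, log-uniform
    abundance_drift: float = 1.0              # multiplicative per labeling window
    abundance_cv: float = 0.05
    missing_rate: float = 0.0
    intensity_cv: float = 0.05
    total_intensity_median: float = 1e6
    total_intensity_sigma: float = 1.0        # ln-units, peptide ion abundance spread
    natural_ria_range: tuple = (0.25, 0.45)
    dh_exp: float = 0.04
    dh_nat: float = kinetics.NATURAL_DH
    n_control_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be a valid (lo, hi) range")
        if not (0.0 <= self.ribosomal_fraction <= 1.0):
            raise ValueError("ribosomal_fraction must be in [0, 1]")
        if self.baseline_fsr_median <= 0 or self.fsr_lognormal_sigma < 0:
            raise ValueError("baseline FSR must be positive, sigma non-negative")
        for m in (
            self.fsr_multipliers,
            self.ribosomal_fsr_multipliers,
            self.ribosomal_abundance_multipliers,
        ):
            if any(v <= 0 for v in m.values()):
                raise ValueError("multipliers must be positive")
        if self.intensity_cv < 0 or self.abundance_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.t1_h <= self.t0_h:
            raise ValueError("t1_h must exceed t0_h")
        if self.control not in self.conditions:
            raise ValueError("control condition must be one of conditions")

    @property
    def enrichment(self) -> kinetics.PrecursorEnrichment:
        return kinetics.PrecursorEnrichment(dh_exp=self.dh_exp, dh_nat=self.dh_nat)

    @property
    def window(self) -> kinetics.LabelingWindow:
        return kinetics.LabelingWindow(t0_h=self.t0_h, t1_h=self.t1_h)


@dataclass
class SimTruth:
    """Ground truth behind one simulated dataset.

    ``proteins`` holds per-protein k_deg per condition (h⁻¹), ribosomal
    membership/subunit and the abundance baseline; ``peptides`` the
    sequences, exchangeable-H counts and natural baseline RIA.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame
    config: SimConfig


@dataclass
class SimDataset:
    truth: SimTruth
    design: pd.DataFrame
    isotopomers: pd.DataFrame
    abundance: pd.DataFrame          # wide write-format frame
    descriptions: pd.DataFrame


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("structure", "abundance", "intensity", "resample")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def build_design(config: SimConfig) -> pd.DataFrame:
    rows = []
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            for t in (config.t0_h, config.t1_h):
                rows.append((f"{cond}_r{rep}_t{int(t)}", cond, rep, float(t), True))
    for rep in range(1, config.n_control_replicates + 1):
        rows.append((f"CTRL_r{rep}", config.control, rep, float(config.t0_h), False))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "replicate", "time_h", "labeled"]
    )


def _fsr_multiplier(config: SimConfig, cond: str, ribosomal: np.ndarray) -> np.ndarray:
    glob = config.fsr_multipliers.get(cond, 1.0)
    ribo = config.ribosomal_fsr_multipliers.get(cond, glob)
    return np.where(ribosomal, ribo, glob)


def generate_proteome(config: SimConfig) -> SimTruth:
    """Draw the protein/peptide structure and true per-condition k_deg."""
    config.validate()
    rng = _streams(config.seed)["structure"]
    n = config.n_proteins
    accessions = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    n_ribo = int(round(config.ribosomal_fraction * n))
    ribo_idx = np.sort(rng.choice(n, size=n_ribo, replace=False))
    is_ribo = np.zeros(n, dtype=bool)
    is_ribo[ribo_idx] = True
    subunit = np.full(n, "", dtype=object)
    descriptions = np.empty(n, dtype=object)
    for j, i in enumerate(ribo_idx):
        su = "40S" if j % 2 == 0 else "60S"
        subunit[i] = su
        prefix = "S" if su == "40S" else "L"
        descriptions[i] = f"{su} ribosomal protein {prefix}{j + 1}"
    for i in np.flatnonzero(~is_ribo):
        descriptions[i] = f"Uncharacterized protein UP{i + 1}"

    k_control = rng.lognormal(
        mean=math.log(config.baseline_fsr_median / 100.0),
        sigma=config.fsr_lognormal_sigma,
        size=n,
    )
    proteins = pd.DataFrame(
        {
            "protein_accession": accessions,
            "description": descriptions,
            "is_ribosomal": is_ribo,
            "subunit": subunit,
            "abundance_baseline": np.exp(
                rng.uniform(
                    math.log(config.abundance_baseline_range[0]),
                    math.log(config.abundance_baseline_range[1]),
                    size=n,
                )
            ),
        }
    )
    for cond in config.conditions:
        mult = 1.0 if cond == config.control else None
        factors = (
            np.ones(n) if mult == 1.0 else _fsr_multiplier(config, cond, is_ribo)
        )
        proteins[f"k_deg_{cond}"] = k_control * factors
    proteins = proteins.set_index("protein_accession", drop=False)

    n_pep = rng.integers(
        config.peptides_per_protein[0], config.peptides_per_protein[1] + 1, size=n
    )
    table = kinetics.load_exchangeable_hydrogens()
    pep_rows = []
    pid = 0
    aa = np.array(list(AA20))
    for i in range(n):
        for _ in range(int(n_pep[i])):
            pid += 1
            length = int(rng.integers(7, 26))
            body = "".join(aa[rng.integers(0, len(aa), size=length - 1)])
            seq = body + _TRYPTIC_END[int(rng.integers(0, 2))]
            pep_rows.append(
                (
                    f"PEP{pid:06d}",
                    accessions[i],
                    seq,
                    kinetics.count_exchangeable_hydrogens(seq, table),
                    float(rng.uniform(*config.natural_ria_range)),
                )
            )
    peptides = pd.DataFrame(
        pep_rows,
        columns=[
            "peptide_id",
            "protein_accession",
            "sequence",
            "n_exchangeable",
            "natural_ria",
        ],
    )
    return SimTruth(proteins=proteins, peptides=peptides, config=config)


def simulate_abundance(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-sample protein abundances (wide frame, labeled samples only).

    Value = baseline × drift^((t−t0)/window) × treatment abundance effect
    (ribosomal subset, end of window only) × mean-one log-normal noise, with
    missingness injected cell-wise at the configured rate.
    """
    if rng is None:
        rng = _streams(config.seed)["abundance"]
    design = build_design(config)
    lab = design[design["labeled"]]
    base = truth.proteins["abundance_baseline"].to_numpy()
    is_ribo = truth.proteins["is_ribosomal"].to_numpy()
    window = config.t1_h - config.t0_h
    values = {}
    for row in lab.itertuples():
        frac = (row.time_h - config.t0_h) / window
        v = base * config.abundance_drift**frac
        if row.time_h == config.t1_h and row.condition != config.control:
            mult = config.ribosomal_abundance_multipliers.get(row.condition, 1.0)
            v = v * np.where(is_ribo, mult, 1.0)
        v = v * _meanone_lognormal(rng, config.abundance_cv, len(v))
        if config.missing_rate > 0:
            v = np.where(rng.random(len(v)) < config.missing_rate, np.nan, v)
        values[row.sample_id] = v
    out = pd.DataFrame(values, index=truth.proteins.index)
    out.insert(0, "description", truth.proteins["description"])
    out.index.name = "protein_accession"
    return out


def _normalized_ratios(
    abundance_wide: pd.DataFrame, design: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Realized P_t1/P_t0 per (protein, condition, replicate) after the
    same inter-sample normalization the analysis applies."""
    values = abundance_wide.drop(columns=["description"], errors="ignore")
    matrix = normalize_intersample(AbundanceMatrix(values=values))
    lab = design[design["labeled"]]
    sample_of = {
        (r.condition, r.replicate, float(r.time_h)): r.sample_id for r in lab.itertuples()
    }
    cols = {}
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            p0 = matrix.values[sample_of[(cond, rep, config.t0_h)]]
            p1 = matrix.values[sample_of[(cond, rep, config.t1_h)]]
            r = (p1 / p0).to_numpy()
            ok = np.isfinite(r) & (p0.to_numpy() > 0) & (p1.to_numpy() > 0)
            cols[(cond, rep)] = np.where(ok, r, 1.0)
    return pd.DataFrame(cols, index=values.index)


def simulate_isotopomer_timecourse(
    truth: SimTruth,
    config: SimConfig,
    abundance_wide: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    resample_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the mass-isotopomer table (and design) for one simulated study.

    Labeled window-start and unlabeled control samples sit at the natural
    baseline RIA; window-end samples follow the exponential rise toward the
    peptide's plateau divided by the realized abundance ratio.  Protein
    draws whose labeling would reach or cross the plateau (rise factor ≥
    abundance ratio) have k_deg redrawn, with a warning, up to a bounded
    number of retries.
    """
    streams = _streams(config.seed)
    if rng is None:
        rng = streams["intensity"]
    if resample_rng is None:
        resample_rng = streams["resample"]
    design = build_design(config)
    peptides = truth.peptides
    n_pep = len(peptides)
    prot_index = truth.proteins.index
    pep_to_prot = prot_index.get_indexer(peptides["protein_accession"])

    if abundance_wide is not None:
        ratios = _normalized_ratios(abundance_wide, design, config)
    else:
        cols = {
            (c, r): np.ones(len(prot_index))
            for c in config.conditions
            for r in range(1, config.n_replicates + 1)
        }
        ratios = pd.DataFrame(cols, index=prot_index)

    nat = peptides["natural_ria"].to_numpy()
    plateau = kinetics.compute_ria_plateau(
        nat, peptides["n_exchangeable"].to_numpy(), config.enrichment
    )
    headroom = plateau - nat
    dt = config.t1_h - config.t0_h

    k = {
        cond: truth.proteins[f"k_deg_{cond}"].to_numpy().copy()
        for cond in config.conditions
    }
    ratio_mat = ratios.to_numpy()  # (n_prot, n_cells)
    min_ratio = ratio_mat.min(axis=1)
    for attempt in range(100):
        bad = np.zeros(len(prot_index), dtype=bool)
        for cond in config.conditions:
            rise = -np.expm1(-k[cond] * dt)
            bad |= rise >= min_ratio
        if not bad.any():
            break
        warnings.warn(
            f"resampling k_deg for {int(bad.sum())} protein(s) whose labeling "
            "would reach the plateau"
        )
        redraw = resample_rng.lognormal(
            mean=math.log(config.baseline_fsr_median / 100.0),
            sigma=config.fsr_lognormal_sigma,
            size=int(bad.sum()),
        )
        is_ribo = truth.proteins["is_ribosomal"].to_numpy()[bad]
        for cond in config.conditions:
            factors = (
                np.ones(int(bad.sum()))
                if cond == config.control
                else _fsr_multiplier(config, cond, is_ribo)
            )
            k[cond][bad] = redraw * factors
    else:
        raise ProteoturnError("could not find plateau-safe k_deg draws")
    for cond in config.conditions:
        truth.proteins[f"k_deg_{cond}"] = k[cond]

    cell_cols = list(ratios.columns)
    cell_pos = {cell: i for i, cell in enumerate(cell_cols)}

    frames = []
    sigma_tot = config.total_intensity_sigma
    mu_tot = math.log(config.total_intensity_median)
    for row in design.itertuples():
        if not row.labeled or row.time_h == config.t0_h:
            ria = nat
        else:
            cell = (row.condition, row.replicate)
            r = ratio_mat[pep_to_prot, cell_pos[cell]]
            kc = k[row.condition][pep_to_prot]
            rise = -np.expm1(-kc * dt)
            ria = nat + headroom * rise / r
        total = rng.lognormal(mean=mu_tot, sigma=sigma_tot, size=n_pep)
        e0 = _meanone_lognormal(rng, config.intensity_cv, n_pep)
        e1 = _meanone_lognormal(rng, config.intensity_cv, n_pep)
        frames.append(
            pd.DataFrame(
                {
                    "peptide_id": peptides["peptide_id"].to_numpy(),
                    "sequence": peptides["sequence"].to_numpy(),
                    "protein_accession": peptides["protein_accession"].to_numpy(),
                    "sample_id": row.sample_id,
                    "time_h": float(row.time_h),
                    "m0": total * (1.0 - ria) * e0,
                    "m1": total * ria * e1,
                }
            )
        )
    isotopomers = pd.concat(frames, ignore_index=True)
    return isotopomers, design


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Full study simulation: proteome, abundances, isotopomers, design."""
    config.validate()
    streams = _streams(config.seed)
    truth = generate_proteome(config)
    abundance = simulate_abundance(truth, config, rng=streams["abundance"])
    isotopomers, design = simulate_isotopomer_timecourse(
        truth,
        config,
        abundance_wide=abundance,
        rng=streams["intensity"],
        resample_rng=streams["resample"],
    )
    descriptions = truth.proteins[["protein_accession", "description"]].reset_index(
        drop=True
    )
    return SimDataset(
        truth=truth,
        design=design,
        isotopomers=isotopomers,
        abundance=abundance,
        descriptions=descriptions,
    )


def write_dataset(dataset: SimDataset, outdir) -> dict[str, Path]:
    """Write all tables of one simulated dataset as CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "isotopomers": outdir / "isotopomers.csv",
        "abundance": outdir / "abundance.csv",
        "design": outdir / "design.csv",
        "descriptions": outdir / "descriptions.csv",
        "truth_proteins": outdir / "truth_proteins.csv",
        "truth_peptides": outdir / "truth_peptides.csv",
    }
    dataset.isotopomers.to_csv(paths["isotopomers"], index=False)
    dataset.abundance.to_csv(paths["abundance"])
    dataset.design.to_csv(paths["design"], index=False)
    dataset.descriptions.to_csv(paths["descriptions"], index=False)
    dataset.truth.proteins.to_csv(paths["truth_proteins"], index=False)
    dataset.truth.peptides.to_csv(paths["truth_peptides"], index=False)
    return paths
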