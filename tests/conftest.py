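import numpy as np
import pandas as pd
import pytest

from proteoturn import kinetics
from proteoturn.simulate import SimConfig, simulate_dataset
from proteoturn.tables import AbundanceMatrix, normalize_intersample


def analyze_dataset(ds, *, abundance=True, ria_t0_mode="control"):
    """Run the kinetics half of the pipeline in memory on a simulated study.

    Returns (peptide kinetics table, long protein-FSR table, normalized
    abundance matrix or None).
    """
    cfg = ds.truth.config
    ab = None
    if abundance:
        ab = normalize_intersample(
            AbundanceMatrix(
                values=ds.abundance.drop(columns="description"),
                descriptions=ds.abundance["description"],
            )
        )
    kin = kinetics.peptide_kinetics_table(
        ds.isotopomers,
        ds.design,
        ab,
        enrichment=cfg.enrichment,
        window=cfg.window,
        ria_t0_mode=ria_t0_mode,
    )
    prot = kinetics.protein_fsr_table(kin)
    return kin, prot, ab


def true_fsr_lookup(truth):
    """(accession, condition) -> true FSR in %/h."""
    out = {}
    for cond in truth.config.conditions:
        col = truth.proteins[f"k_deg_{cond}"]
        for acc, k in col.items():
            out[(acc, cond)] = 100.0 * k
    return out


@pytest.fixture(scope="session")
def small_noiseless_dataset():
    cfg = SimConfig(
        seed=902,
        n_proteins=40,
        peptides_per_protein=(1, 4),
        intensity_cv=0.0,
        abundance_cv=0.0,
        abundance_drift=1.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def design_frame():
    rows = []
    for cond in ("VC", "IBU", "PEA"):
        for rep in (1, 2, 3):
            for t in (12.0, 36.0):
                rows.append((f"{cond}_r{rep}_t{int(t)}", cond, rep, t, True))
    for rep in (1, 2, 3):
        rows.append((f"CTRL_r{rep}", "VC", rep, 12.0, False))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "replicate", "time_h", "labeled"]
    )
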