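"""Shared fixtures: seeded synthetic datasets with planted ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from pgpscan import AxisProfile, fit_model
from pgpscan.core import MotifModel
from pgpscan.hmm import crm_motif_score
from pgpscan.model import ExpressionModel, default_covariate_spec
from pgpscan.simulate import (
    Plant,
    constructive_baselines,
    make_concentrations,
    make_locus,
    make_motif,
    plant_sites,
    random_sequence,
    simulate_expression,
    simulate_training_data,
)

# ----------------------------------------------------------- small helpers


@pytest.fixture(scope="session")
def training_data():
    """Standard 10 TF x 46 CRM x 100 bin training collection."""
    return simulate_training_data(seed=11)


@pytest.fixture(scope="session")
def noisy_training_data():
    return simulate_training_data(seed=11, noise=0.1)


@pytest.fixture(scope="session")
def fitted_model(training_data):
    model, report = fit_model(
        training_data.S,
        training_data.concentrations,
        training_data.targets_clean,
        training_data.covariate_spec,
    )
    return model, report


# ------------------------------------------------------ discovery study

DISCOVERY_SHAPES = {"actA": "anterior", "actB": "posterior", "rep": "stripe:40:60"}
DISCOVERY_WEIGHTS = {"actA": 0.35, "actB": 0.35, "rep": -0.5}
LOCUS_LENGTH = 6000
CRM_LENGTH = 1000
PLANT_SITES = {"actA": 8, "rep": 3}


@dataclass
class DiscoveryStudy:
    motifs: dict
    concentrations: pd.DataFrame
    weights: dict
    covariate_spec: list
    model: ExpressionModel
    null_pgp: np.ndarray
    gene_expr: AxisProfile

    def gene_pattern(self, s_row: dict) -> AxisProfile:
        S1 = pd.DataFrame([s_row], index=["g"])
        base = constructive_baselines(
            S1, self.concentrations, self.weights, self.covariate_spec
        )
        clean, _ = simulate_expression(
            S1, self.concentrations, self.weights, base, self.covariate_spec
        )
        return AxisProfile(clean.loc["g"].to_numpy(), "binary", "gene")


def build_discovery_study(
    seed: int = 77, n_training: int = 12, n_null_loci: int = 12
) -> DiscoveryStudy:
    """Train a 3-TF model on scored synthetic CRMs and scan background
    loci once to form the null PGP window set."""
    from pgpscan.discovery import scan_locus

    motifs = {
        tf: make_motif(101 + i, width=8, strength=1.5, name=tf)
        for i, tf in enumerate(DISCOVERY_SHAPES)
    }
    conc = make_concentrations(DISCOVERY_SHAPES)
    spec = default_covariate_spec(list(DISCOVERY_SHAPES))
    rng = np.random.default_rng(seed)
    rows = {}
    for k in range(n_training):
        counts = {
            "actA": int(rng.integers(0, 9)),
            "actB": int(rng.integers(0, 9)),
            "rep": int(rng.integers(0, 5)),
        }
        seq = plant_sites(random_sequence(CRM_LENGTH, rng), counts, motifs, rng)
        rows[f"t{k}"] = {tf: crm_motif_score(seq, m) for tf, m in motifs.items()}
    S = pd.DataFrame(rows).T
    base = constructive_baselines(S, conc, DISCOVERY_WEIGHTS, spec)
    clean, _ = simulate_expression(S, conc, DISCOVERY_WEIGHTS, base, spec)
    model, _ = fit_model(S, conc, clean, spec)
    # reference gene pattern: an anterior-activator CRM
    _, _, Sp = make_locus(
        seed + 5000, LOCUS_LENGTH,
        [Plant(start=2500, sites=PLANT_SITES, length=CRM_LENGTH)], motifs,
    )
    study = DiscoveryStudy(
        motifs=motifs,
        concentrations=conc,
        weights=DISCOVERY_WEIGHTS,
        covariate_spec=spec,
        model=model,
        null_pgp=np.array([]),
        gene_expr=None,  # set below
    )
    study.gene_expr = study.gene_pattern(Sp.iloc[0].to_dict())
    null = []
    for k in range(n_null_loci):
        seq = random_sequence(LOCUS_LENGTH, np.random.default_rng(seed + 600 + k))
        preds = scan_locus(study.gene_expr, seq, model, motifs, conc)
        null.extend(p.pgp for p in preds)
    study.null_pgp = np.array(null)
    return study


@pytest.fixture(scope="session")
def discovery_study():
    return build_discovery_study()


@pytest.fixture
def consensus_motif():
    """Near-deterministic width-8 PWM (ACGT-alternating consensus)."""
    m = np.full((8, 4), 0.01)
    for k in range(8):
        m[k, k % 4] = 0.97
    return MotifModel(m, name="cons8")
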