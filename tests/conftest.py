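"""Shared fixtures: small synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stressfactor as sf


@pytest.fixture(scope="session")
def planted_study():
    """A planted-effects study at 5 replicates/cell (strong recovery regime)."""
    cfg = sf.SimulationConfig(
        n_genes=800, n_masses=200, replicates_per_cell=5, seed=11
    )
    t, m, design, truth = sf.generate_paired_dataset(cfg)
    return {"config": cfg, "transcriptome": t, "metabolome": m,
            "design": design, "truth": truth}


@pytest.fixture(scope="session")
def latent_study():
    """A study with drought- and heat-driven latent cross-omics factors."""
    cfg = sf.SimulationConfig(
        n_genes=300, n_masses=120, replicates_per_cell=3,
        group_proportions={}, humidity_responsive_fraction=0.0,
        noise_sd=0.2,
        latent_factors=(
            sf.LatentFactorSpec(n_genes=25, n_masses=8, loading=1.5,
                                driver="drought", score_noise=0.15),
            sf.LatentFactorSpec(n_genes=25, n_masses=8, loading=0.8,
                                driver="heat", score_noise=0.15),
        ),
        seed=23,
    )
    t, m, design, truth = sf.generate_paired_dataset(cfg)
    return {"config": cfg, "transcriptome": t, "metabolome": m,
            "design": design, "truth": truth}


@pytest.fixture()
def balanced_design():
    """Minimal balanced factorial design: 4 conditions x 3 replicates."""
    rows = []
    i = 0
    for cond, (d, h, hum) in {
        "control": (0, 0, "ambient"), "D": (1, 0, "ambient"),
        "H_LrH": (0, 1, "low"), "DH_LrH": (1, 1, "low"),
    }.items():
        for rep in range(3):
            rows.append({
                "sample_id": f"x{i}", "drought": d, "heat": h,
                "humidity": hum, "genotype": "WT", "batch": f"b{rep + 1}",
            })
            i += 1
    return sf.validate_design(pd.DataFrame(rows))


def make_matrix(values, layer="transcriptome", scale="log2", mask=None,
                prefix="v", sample_prefix="x"):
    values = np.asarray(values, dtype=float)
    return sf.OmicsMatrix(
        values,
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"{sample_prefix}{j}" for j in range(values.shape[1])],
        missing_mask=mask, layer=layer, scale=scale,
    )
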