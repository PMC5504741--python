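"""Synthetic paired transcriptome/metabolome generator with ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes: a 6-condition design (control, D, H_LrH, H_HrH, DH_LrH, DH_HrH)
crossed with genotypes that carry no effect, additive batch offsets,
variables planted into the factorial response groups through true
(betaD, betaH, betaDH) coefficients, a humidity ("dry-air") term that
separates the high- from the low-humidity heat cells, latent factors that
induce cross-omics correlation, and below-floor censoring of metabolite
intensities.  Every random draw flows from a single integer seed, so a
given configuration is byte-reproducible.

Expression of variable g in sample s, on the log2 scale:

    y_gs = baseline_g + betaD*D_s + betaH*H_s + betaDH*D_s*H_s
           + humidity term + batch offset + sum_f loading_gf * score_fs
           + Normal(0, noise_sd)

The metabolome layer is generated the same way, exponentiated to raw scale
and censored below the detection floor, so the detection filter and floor
imputation stages are exercised realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .design import CONDITIONS, validate_design
from .io import AnnotationSets
from .matrix import OmicsMatrix

#: default planted fractions per response group; the remainder is null
DEFAULT_GROUP_PROPORTIONS: dict[str, float] = {
    "2.1": 0.05, "2.2": 0.02, "2.3": 0.015,
    "1.1": 0.01, "1.2": 0.01, "1.3": 0.01,
    "3.1": 0.015, "3.2": 0.01, "3.3": 0.01,
    "4": 0.02,
    "opp_additive": 0.002, "opp_interaction": 0.002,
}


@dataclass(frozen=True)
class LatentFactorSpec:
    """One latent cross-omics factor.

    ``driver`` decides the factor scores: ``drought``/``heat`` tie the
    factor to the corresponding stress indicator (plus score noise),
    ``random`` draws iid standard-normal scores.
    """

    n_genes: int = 20
    n_masses: int = 5
    loading: float = 1.0
    driver: str = "random"
    score_noise: float = 0.3

    def __post_init__(self) -> None:
        if self.driver not in ("drought", "heat", "random"):
            raise ValueError(f"unknown driver {self.driver!r}")
        if self.n_genes < 0 or self.n_masses < 0:
            raise ValueError("member counts must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic paired-omics study."""

    n_genes: int = 2000
    n_masses: int = 300
    replicates_per_cell: int = 3
    genotypes: tuple[str, ...] = ("WT", "DM", "TM")
    n_batches: int = 3
    batch_sd: float = 0.5
    group_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS)
    )
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"D": 2.5, "H": 2.5, "DH": 2.5}
    )
    noise_sd: float = 0.3
    latent_factors: tuple[LatentFactorSpec, ...] = ()
    humidity_effect: float = 2.0
    humidity_responsive_fraction: float = 0.05
    gene_baseline: tuple[float, float] = (10.0, 1.5)   # log2 mean, sd
    mass_baseline: tuple[float, float] = (21.0, 1.5)   # log2 mean, sd
    detection_floor: float = 5.0e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        props = self.group_proportions
        if any(v < 0 for v in props.values()):
            raise ValueError("group proportions must be non-negative")
        if sum(props.values()) > 1.0 + 1e-12:
            raise ValueError("group proportions exceed 1")
        if self.replicates_per_cell < 1 or self.n_batches < 1:
            raise ValueError("replicates and batches must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth exported beside the generated data."""

    variables: pd.DataFrame          # per variable: layer, group, direction,
                                     # true betas, latent factor, humidity flag
    batch_offsets: dict[str, dict[str, float]]   # layer -> batch -> offset
    factor_scores: pd.DataFrame      # samples x factors

    def layer(self, name: str) -> pd.DataFrame:
        return self.variables[self.variables["layer"] == name]


def _make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for cond in CONDITIONS:
        for gt in config.genotypes:
            for rep in range(config.replicates_per_cell):
                drought = int(cond in ("D", "DH_LrH", "DH_HrH"))
                heat = int(cond in ("H_LrH", "H_HrH", "DH_LrH", "DH_HrH"))
                if not heat:
                    humidity = "ambient"
                else:
                    humidity = "low" if cond.endswith("LrH") else "high"
                rows.append({
                    "sample_id": f"s{i:03d}",
                    "drought": drought,
                    "heat": heat,
                    "humidity": humidity,
                    "genotype": gt,
                    "batch": f"b{rep % config.n_batches + 1}",
                    "order": i,
                })
                i += 1
    return validate_design(pd.DataFrame(rows))


_GROUP_BETAS = {
    # group -> (multiplier on |betaD|, |betaH|, |betaDH|), relative to the
    # variable's direction sign s; reduced rows counteract, enhanced reinforce
    "2.1": (1, 0, 0), "3.1": (1, 0, 1), "1.1": (1, 0, -1),
    "2.2": (1, 1, 0), "3.2": (1, 1, 1), "1.2": (1, 1, -1),
    "2.3": (0, 1, 0), "3.3": (0, 1, 1), "1.3": (0, 1, -1),
    "4": (0, 0, 1),
    "opp_additive": (1, -1, 0), "opp_interaction": (1, -1, -1),
    "null": (0, 0, 0),
}


def _assign_groups(
    n: int, proportions: dict[str, float], rng: np.random.Generator
) -> list[str]:
    labels = []
    for g, frac in proportions.items():
        labels.extend([g] * int(round(frac * n)))
    if len(labels) > n:
        labels = labels[:n]
    labels.extend(["null"] * (n - len(labels)))
    rng.shuffle(labels)
    return labels


def generate_paired_dataset(
    config: SimulationConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, pd.DataFrame, GroundTruth]:
    """Generate (transcriptome, metabolome, design, truth) for one study."""
    rng = np.random.default_rng(config.seed)
    design = _make_design(config)
    n_samples = len(design)
    D = design["drought"].to_numpy(float)
    H = design["heat"].to_numpy(float)
    high_hum = (design["humidity"] == "high").to_numpy(float)
    batch_codes = design["batch"].to_numpy()
    batches = sorted(set(batch_codes))

    eD = config.effect_sizes.get("D", 2.5)
    eH = config.effect_sizes.get("H", 2.5)
    eI = config.effect_sizes.get("DH", 2.5)

    # factor scores, one column per latent factor
    scores = np.zeros((n_samples, len(config.latent_factors)))
    for f, spec in enumerate(config.latent_factors):
        if spec.driver == "drought":
            base = D - D.mean()
        elif spec.driver == "heat":
            base = H - H.mean()
        else:
            base = rng.standard_normal(n_samples)
        base = base / max(base.std(), 1e-12)
        scores[:, f] = base + spec.score_noise * rng.standard_normal(n_samples)

    def make_layer(
        prefix: str, n_var: int, baseline: tuple[float, float], layer: str
    ) -> tuple[np.ndarray, pd.DataFrame, dict[str, float]]:
        ids = [f"{prefix}{i:05d}" for i in range(n_var)]
        groups = _assign_groups(n_var, config.group_proportions, rng)
        signs = rng.choice([-1.0, 1.0], size=n_var)
        beta = np.zeros((n_var, 3))
        for i, g in enumerate(groups):
            mult = _GROUP_BETAS[g]
            beta[i] = signs[i] * np.array(
                [mult[0] * eD, mult[1] * eH, mult[2] * eI]
            )
        hum_flag = rng.random(n_var) < config.humidity_responsive_fraction
        hum_sign = rng.choice([-1.0, 1.0], size=n_var)
        hum_effect = np.where(hum_flag, hum_sign * config.humidity_effect, 0.0)
        baselines = baseline[0] + baseline[1] * rng.standard_normal(n_var)
        offsets = {b: float(config.batch_sd * rng.standard_normal()) for b in batches}
        batch_vec = np.array([offsets[b] for b in batch_codes])

        values = (
            baselines[:, None]
            + beta[:, 0:1] * D[None, :]
            + beta[:, 1:2] * H[None, :]
            + beta[:, 2:3] * (D * H)[None, :]
            + hum_effect[:, None] * (H * high_hum)[None, :]
            + batch_vec[None, :]
            + config.noise_sd * rng.standard_normal((n_var, n_samples))
        )

        # latent-factor loadings, drawn from the planted-null pool so group
        # membership and factor membership stay disentangled
        factor_of = np.full(n_var, -1)
        null_pool = [i for i, g in enumerate(groups) if g == "null" and not hum_flag[i]]
        rng.shuffle(null_pool)
        cursor = 0
        for f, spec in enumerate(config.latent_factors):
            want = spec.n_genes if layer == "transcriptome" else spec.n_masses
            if cursor + want > len(null_pool):
                raise ValueError(
                    "not enough null variables to host the latent factors"
                )
            members = null_pool[cursor:cursor + want]
            cursor += want
            factor_of[members] = f
            values[members, :] += spec.loading * scores[:, f][None, :]

        truth = pd.DataFrame({
            "variable_id": ids,
            "layer": layer,
            "group": groups,
            "direction": [
                "none" if g == "null"
                else ("mixed" if g.startswith("opp") else ("up" if s > 0 else "down"))
                for g, s in zip(groups, signs)
            ],
            "beta_D": beta[:, 0],
            "beta_H": beta[:, 1],
            "beta_DH": beta[:, 2],
            "humidity_responsive": hum_flag,
            "humidity_effect": hum_effect,
            "latent_factor": factor_of,
        })
        return values, truth, offsets

    sample_ids = design["sample_id"].tolist()
    g_values, g_truth, g_offsets = make_layer(
        "G", config.n_genes, config.gene_baseline, "transcriptome"
    )
    m_values, m_truth, m_offsets = make_layer(
        "M", config.n_masses, config.mass_baseline, "metabolome"
    )

    transcriptome = OmicsMatrix(
        g_values, g_truth["variable_id"].tolist(), sample_ids,
        layer="transcriptome", scale="log2",
    )
    raw = np.power(2.0, m_values)
    mask = raw < config.detection_floor
    raw = np.where(mask, np.nan, raw)
    metabolome = OmicsMatrix(
        raw, m_truth["variable_id"].tolist(), sample_ids,
        missing_mask=mask, layer="metabolome", scale="raw",
    )

    truth = GroundTruth(
        variables=pd.concat([g_truth, m_truth], ignore_index=True),
        batch_offsets={"transcriptome": g_offsets, "metabolome": m_offsets},
        factor_scores=pd.DataFrame(
            scores, index=sample_ids,
            columns=[f"F{f}" for f in range(scores.shape[1])],
        ),
    )
    return transcriptome, metabolome, design, truth


def generate_annotation_sets(
    truth: GroundTruth,
    planted_group: str = "2.1",
    layer: str = "transcriptome",
    term_size: int = 50,
    enrichment_fold: float = 4.0,
    n_random_terms: int = 19,
    random_term_size: tuple[int, int] = (20, 80),
    seed: int = 0,
) -> AnnotationSets:
    """Annotation term sets with one term planted to overlap a group.

    The planted term draws ``fold`` times the chance expectation of its
    members from ``planted_group``; the remaining terms are uniform draws
    from the layer's variables.  ``fold = 1`` reduces to a random term.
    """
    rng = np.random.default_rng(seed)
    layer_truth = truth.layer(layer)
    universe = layer_truth["variable_id"].tolist()
    N = len(universe)
    if term_size <= 0:
        raise ValueError("term size must be positive")
    if term_size > N:
        raise ValueError(f"term size {term_size} exceeds {N} variables")
    group_members = layer_truth.loc[
        layer_truth["group"] == planted_group, "variable_id"
    ].tolist()
    if not group_members:
        raise ValueError(f"no variables in group {planted_group!r}")
    expected = term_size * len(group_members) / N
    overlap = int(round(min(enrichment_fold * expected, term_size, len(group_members))))
    others = [v for v in universe if v not in set(group_members)]
    planted = (
        list(rng.choice(group_members, size=overlap, replace=False))
        + list(rng.choice(others, size=term_size - overlap, replace=False))
    )
    term_ids = ["T_planted"]
    names = {"T_planted": f"planted:{planted_group}"}
    members = {"T_planted": frozenset(planted)}
    lo, hi = random_term_size
    for t in range(n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        tid = f"T{t:03d}"
        term_ids.append(tid)
        names[tid] = "random"
        members[tid] = frozenset(rng.choice(universe, size=size, replace=False))
    return AnnotationSets(term_ids, names, members)


def evaluate_group_recovery(
    result: pd.DataFrame, truth: GroundTruth, layer: str = "transcriptome"
) -> dict:
    """Compare recovered response groups with the planted truth.

    Returns per-group sensitivity (true members receiving their exact
    label), the false-discovery proportion among declared-regulated
    variables, and the adjusted Rand index of the two labelings.
    """
    t = truth.layer(layer).set_index("variable_id")
    if set(result.index) != set(t.index):
        raise ValueError("variable ids of result and truth do not match")
    t = t.loc[result.index]
    true_g = t["group"].to_numpy()
    called_g = result["group"].to_numpy()

    sensitivity = {}
    for g in sorted(set(true_g) - {"null"}):
        mask = true_g == g
        sensitivity[g] = float((called_g[mask] == g).mean())
    declared = called_g != "null"
    n_declared = int(declared.sum())
    fdp = (
        float(((true_g == "null") & declared).sum() / n_declared)
        if n_declared else 0.0
    )
    return {
        "sensitivity": sensitivity,
        "false_discovery_proportion": fdp,
        "n_declared": n_declared,
        "adjusted_rand_index": float(adjusted_rand_score(true_g, called_g)),
    }


def evaluate_partition(labels: dict, reference: dict) -> dict:
    """Adjusted Rand index between a community partition and a reference."""
    if set(labels) != set(reference):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(labels)
    return {
        "adjusted_rand_index": float(adjusted_rand_score(
            [reference[n] for n in nodes], [labels[n] for n in nodes]
        )),
        "n_nodes": len(nodes),
    }
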