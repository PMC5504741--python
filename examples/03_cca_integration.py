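"""Integrate transcriptome and metabolome by regularized CCA.

Plants a drought-driven and a weaker heat-driven latent factor shared by
both layers, then checks that the first canonical component separates
drought from non-drought samples and the second separates heat from
non-heat -- without the model ever seeing the condition labels.
"""

from sklearn.metrics import roc_auc_score

import stressfactor as sf

cfg = sf.SimulationConfig(
    n_genes=300, n_masses=120, replicates_per_cell=3,
    group_proportions={}, humidity_responsive_fraction=0.0, noise_sd=0.2,
    latent_factors=(
        sf.LatentFactorSpec(n_genes=25, n_masses=8, loading=1.5,
                            driver="drought", score_noise=0.15),
        sf.LatentFactorSpec(n_genes=25, n_masses=8, loading=0.8,
                            driver="heat", score_noise=0.15),
    ),
    seed=5)
transcriptome, metabolome, design, truth = sf.generate_paired_dataset(cfg)
metabolome = sf.impute_floor_and_log(
    sf.filter_by_detection(sf.tic_normalize(metabolome), design))

x, y = sf.pair_samples(transcriptome, metabolome)
x = sf.select_top_variance(x, 50)
y = sf.select_top_variance(y, min(50, y.n_variables))
model = sf.fit_rcca(x, y, n_components=2)

print(f"shrinkage regularization: lambda_x={model.lambda_x:.3f}, "
      f"lambda_y={model.lambda_y:.3f}")
print("canonical correlations:",
      [round(float(r), 3) for r in model.canonical_correlations])

d = design.set_index("sample_id").loc[model.x_scores.index]
auc_d = roc_auc_score(d["drought"], model.x_scores["CC1"])
auc_h = roc_auc_score(d["heat"], model.x_scores["CC2"])
print(f"component 1 separates drought (AUC {max(auc_d, 1 - auc_d):.3f}); "
      f"component 2 separates heat (AUC {max(auc_h, 1 - auc_h):.3f})")

# which original variables load on component 1?
table = sf.variate_variable_correlations(model, x, y)
cc1 = table[(table["component"] == "CC1") & (table["layer"] == "x")]
top = cc1.reindex(cc1["r"].abs().sort_values(ascending=False).index).head(5)
print("\ntop genes correlated with canonical component 1:")
print(top[["variable_id", "r", "p_adjusted"]].to_string(index=False))
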