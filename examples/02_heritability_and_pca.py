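"""Broad-sense heritability, adjusted means and PCA of seed profiles.

Fits amount ~ accession + replicate + plate per compound and partitions
the sum of squares; H2 is the accession share.  Adjusted per-accession
means feed a scaled PCA of the accession x compound matrix.
"""

import aragsl as ag

config = ag.SimulationConfig(n_accessions=300, seed=2)
truth = ag.simulate_accessions(config)
measurements = ag.simulate_profiles(truth, config)

herit = ag.estimate_heritability(measurements)
print(f"median H2 across {len(herit.shares)} compounds: {herit.median_h2:.2f}")
print("\nfive most heritable compounds:")
print(
    herit.shares.sort_values("h2", ascending=False)
    .head(5)[["compound", "h2", "share_residual"]]
    .to_string(index=False)
)

emmeans = ag.compute_emmeans(measurements)
pca = ag.run_pca(emmeans, scale=True)
pc12 = 100 * pca.variance_explained[:2].sum()
print(f"\nPC1+PC2 capture {pc12:.1f}% of the variation")
# A minority share is expected: the seven discrete chemotypes form a
# multimodal cloud that a two-component linear summary cannot flatten --
# the reason the pipeline classifies chemotypes directly instead of
# relying on PC scores.
print("\ntop PC1 loadings:")
print(pca.loadings["PC1"].abs().sort_values(ascending=False).head(4).to_string())
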