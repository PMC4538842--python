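"""Generalized correlation coefficients and a thresholded network.

Samples a Gaussian ensemble of pseudo-Cα/C5' atoms with a planted
correlated group spanning protein and DNA, estimates the mutual-
information generalized correlation matrix, checks sampling convergence
via cosine content, and counts protein-DNA edges at the 0.7 threshold.
"""

import numpy as np

import topotraj as tt

kinds = ["protein"] * 5 + ["dna"] * 3
group = [1, 2, 5, 6]  # two Cα and two C5' atoms moving together
rho = tt.block_correlation_matrix(8, [group], rho_within=0.85)
ensemble = tt.sample_correlated_ensemble(
    tt.EnsembleRecipe(
        8, 4000, seed=7, covariance=tt.isotropic_correlation_cov(rho), kinds=kinds
    )
)

model = tt.covariance_pca(ensemble)
report = tt.convergence_report(model, ensemble)
print("cosine contents (PC1-3):", [round(c, 3) for c in report.cosine_contents])
print("adequately sampled     :", report.converged)

matrix = tt.correlation_matrix(ensemble, None)
graph, counts = tt.build_network(matrix, threshold=0.7)
print("edges >= 0.7           :", counts.n_edges)
print("protein-DNA edges      :", counts.protein_dna)
print("planted pair r values  :",
      [round(float(matrix.values[1, 5]), 2), round(float(matrix.values[2, 6]), 2)])
# Low cosine content says the ensemble is not diffusion-like (adequate
# sampling); the protein-DNA edge count recovers exactly the planted
# correlated Cα-C5' pairs.
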