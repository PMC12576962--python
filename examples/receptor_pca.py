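"""Build receptor-density regressors: layer averaging, z-scoring, PCA.

A synthetic regional receptor-density table (regions x receptors x
cortical layers) is reduced to principal-component scores, which then
become channel-level covariates through the region membership of each
channel.
"""

from spectralcmc import cohort, receptors

table = cohort.generate_receptor_table(n_regions=40, n_receptors=15,
                                       latent_dim=4, seed=1)
print(f"table: {len(table.region_labels)} regions x "
      f"{len(table.receptor_labels)} receptors x 3 layers")

matrix = receptors.normalize_columns(receptors.average_layers(table),
                                     table.region_labels,
                                     table.receptor_labels)
basis = receptors.principal_components(matrix, 6)
print("explained variance fractions:",
      ", ".join(f"{x:.3f}" for x in basis.explained_fraction[:6]))
print("cumulative PC1-4:", f"{basis.explained_fraction[:4].sum():.3f}")

# Channel-level design matrix: two channels in each of the first 3 regions
channel_ids = [f"ch{i}" for i in range(6)]
channel_map = {cid: table.region_labels[i // 2]
               for i, cid in enumerate(channel_ids)}
scores = receptors.map_channels_to_regions(
    channel_ids, channel_map, table.region_labels, basis.scores)
design = receptors.build_design_matrix(
    scores[:, :4], channel_ids, ["PC1", "PC2", "PC3", "PC4"])
print("design matrix shape (mean column + 4 PCs):", design.values.shape)

# The 15 candidate receptor-subset designs used in subset model comparison
subsets = receptors.enumerate_receptor_subsets()
print(f"{len(subsets)} receptor subsets, e.g. {subsets[:3]} ...")
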