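"""Copy-number profiles, Ward clustering, and retention classes.

Simulates 10 gene families per retention class on the bundled angiosperm
species tree, splits them into orthogroups, and shows that the families
generated with high WGD retention cluster apart from the low-retention
ones and are classified multi-copy.
"""

import paleologs as pl

species = pl.default_species_tree()
config = pl.SimulationConfig(seed=4, families_per_class=10)
families = [f for f in pl.simulate_dataset(config, species) if not f.extinct]

trees, maps, ids, truth = [], [], [], []
for fam in families:
    rec = pl.reconcile(fam.gene_tree, species, fam.gene_species_map)
    for i, sub in enumerate(pl.split_aogs(rec, "Angiosperms")):
        trees.append(sub)
        maps.append({l: fam.gene_species_map[l] for l in sub.leaf_labels()})
        ids.append(f"{fam.family_id}.{i}")
        truth.append(fam.class_label)

matrix = pl.build_copy_matrix(trees, maps, species.species(), ids)
clusters = pl.ward_cluster(matrix, 2)
classes = pl.classify_matrix(matrix, species.metadata)

summary = matrix.copy()
summary["cluster"] = clusters
summary["class"] = classes
summary["truth"] = truth
print(summary.to_string())
print(
    "\n-> AOGs from high-retention (broad) families carry ~4 copies in"
    " WGD-covered species and fall in one Ward cluster / the multi class;"
    " low-retention families stay near single-copy."
)
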