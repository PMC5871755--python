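"""Phylogenetic beta diversity: UniFrac, PCoA, and perMANOVA.

Two distinct communities, four replicate libraries each, sequenced
error-free, classified, and compared with generalized UniFrac; perMANOVA
(exact enumeration over the 70 label splits) tests the group separation.
"""

import amplicord as ac

db = ac.build_reference_db(n_taxa=20, n_confusable_groups=4, group_size=2, seed=1)
index = ac.ReferenceIndex(ac.db_records(db))
lineages = ac.db_lineages(db)

tables, labels = [], []
for group, profile_seed in (("A", 101), ("B", 202)):
    profile = ac.sample_community(db, "lognormal", n_taxa=8, seed=profile_seed)
    for rep in range(4):
        renamed = ac.CommunityProfile(profile.composition, sample_name=f"{group}{rep}")
        config = ac.long_read_config(400, seed=1000 + 10 * rep + ord(group), error_scale=0.0)
        reads, _ = ac.simulate_long_reads(db, renamed, config)
        results = ac.classify_reads(reads, index)
        tables.append(ac.classification_table(results, lineages, sample_name=f"{group}{rep}"))
        labels.append(group)

table = ac.combine_single_sample_tables(tables)
tree = ac.reference_tree([index[t] for t in table.taxa])
for variant in ("d_W", "d_0.5", "d_U"):
    dm = ac.unifrac_matrix(table, tree, variants=(variant,))[variant]
    ordination = ac.pcoa(dm)
    result = ac.permanova(dm, labels, exact=True)
    pc1 = ordination.proportion_explained[0] if ordination.proportion_explained else 0
    print(
        f"{variant:6s} pseudo-F = {result.pseudo_f:8.2f}  p = {result.p_value:.4f}  "
        f"PC1 explains {pc1:.0%}"
    )
# Weighted variants separate the two compositions at the smallest p the
# 4+4 design allows (2/70 ~= 0.029); PC1 carries most of the variance.
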