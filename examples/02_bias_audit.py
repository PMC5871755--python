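"""The error-free recreated-dataset bias audit.

Rebuilds each identified taxon's exact reference sequence, extracts the
V3-V4 region a short-read library would see, reclassifies those regions by
both analysis paths, and counts how many come back under a different
accession. Taxa identical across V3-V4 but distinct elsewhere are the sole
source of discordance.
"""

import amplicord as ac
from amplicord.insilico_pcr import SHORT_READ_PRIMERS

db = ac.build_reference_db(n_taxa=20, n_confusable_groups=4, group_size=2, seed=1)
report = ac.bias_audit(
    ac.db_records(db), [t.accession for t in db], SHORT_READ_PRIMERS
)

for path, venn in report.venn.items():
    print(
        f"{path:28s} {venn.n_concordant}/{venn.n_total} concordant, "
        f"{venn.pct_discordant:.2f}% discordant"
    )
print(
    f"clustering collapsed {report.n_input_sequences} unique regions to "
    f"{report.n_unique_after_clustering}"
)
# Full-length sequences always return home (0% discordant); the V3-V4
# region loses one member of each identical pair (4/20 = 20.00%) to the
# deterministic tie-break — the mechanism by which short reads understate
# species-level diversity.
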