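"""Cluster 16S sequences into OTUs at 100/99/98% identity.

A small community with three planted genera is clustered at the three
identity thresholds. The OTU count drops as the threshold loosens: 100%
separates every distinct sequence (dereplication), 99% should recover the
planted genera, and 98% can merge no further here because the genus
templates are >5% apart.
"""
from actinoprint import (
    SequenceRecord,
    cluster_otus,
    composition_summary,
    dereplicate,
    generate_community,
    identity_matrix,
)
from actinoprint.synthetic import CommunityConfig, GenusSpec, make_templates

templates = make_templates(n=3, length=800, seed=11)
spec = [
    GenusSpec(name, 1 / 3, tid)
    for name, tid in zip(["Streptomyces", "Micromonospora", "Nocardiopsis"], templates)
]
config = CommunityConfig(
    n_isolates=12, genus_spec=spec, templates=templates,
    gene_prevalence={g.name: (0.0, 0.0) for g in spec}, seed=11,
)
records = generate_community(config)

seqs = [SequenceRecord(r.isolate_id, "", r.sixteenS) for r in records]
matrix = identity_matrix(seqs)
for threshold in (1.0, 0.99, 0.98):
    partition = cluster_otus(matrix, threshold)
    print(f"identity {threshold * 100:5.1f}% -> {partition.n_otus:2d} OTUs")

_, duplicates = dereplicate(cluster_otus(matrix, 1.0))
print(f"duplicates removed by dereplication: {duplicates}")

genus_of = {r.isolate_id: r.genus for r in records}
print("\ngenus composition of OTUs at 99% (percent of all OTUs):")
print(composition_summary(cluster_otus(matrix, 0.99), genus_of).to_string(index=False))
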