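"""OTU analysis of a deposited 16S collection (requires a manual download).

The deposited 16S sequences of the study this workflow models are GenBank
accessions KX352755-KX352820 (66 partial 16S rRNA genes, ~1,300 nt). This
script is the recipe for re-running the OTU analysis on them; it needs a
FASTA you fetch yourself, e.g.:

    # with NCBI EDirect installed and network access:
    efetch -db nuccore -id "KX352755:KX352820[ACCN]" -format fasta \
        > deposited_16S.fasta

    python examples/deposited_data.py deposited_16S.fasta

Expected behaviour: clustering at 100/99/98% identity yields 62/39/25 OTUs
(the 99/98% counts can shift by ~1 with alignment-parameter choices, since
the original tool's linkage is not documented). Pairwise spot checks:
JJ135 (KX352813) vs Glycomyces arizonensis NRRL B-16153(T) ~97.6% identity,
JJ50 (KX352790) vs Nocardia amamiensis TT 00-78(T) ~98.5%.
"""
import sys

from actinoprint import cluster_otus, dereplicate, identity_matrix, read_fasta

if len(sys.argv) != 2:
    sys.exit(__doc__)

seqs = read_fasta(sys.argv[1])
print(f"{len(seqs)} sequences loaded")
matrix = identity_matrix(seqs)
lengths = {s.id: len(s.residues) for s in seqs}
for threshold in (1.0, 0.99, 0.98):
    partition = cluster_otus(matrix, threshold, lengths)
    print(f"identity {threshold * 100:5.1f}% -> {partition.n_otus} OTUs")
_, duplicates = dereplicate(cluster_otus(matrix, 1.0, lengths))
print(f"duplicates at 100% identity: {duplicates}")
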