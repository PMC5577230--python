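"""OTU analysis of marker-gene sequences.

Pairwise identity is computed from an end-gap-free global alignment
(Needleman-Wunsch with zero-cost terminal gaps), so sequences trimmed to
different lengths are compared only over the region they share. Sequences
are grouped into operational taxonomic units (OTUs) by complete-linkage
agglomerative clustering on 1 - identity: a cut at threshold *t* then
guarantees that every within-cluster pair has identity >= t, which is the
defining property of a threshold OTU. Typical thresholds for actinobacterial
16S work are 1.00 (dereplication), 0.99 and 0.98.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .dna import IUPAC_DNA, IUPAC_SETS
from .io import SequenceRecord
from .util import ParameterError, percent


@dataclass
class AlignmentParams:
    """Scores for the end-gap-free global alignment behind identity values."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class OTUPartition:
    """A clustering of sequences at one identity threshold."""

    threshold: float
    clusters: list[list[str]]
    representatives: list[str]

    @property
    def n_otus(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        return {sid: k for k, members in enumerate(self.clusters) for sid in members}


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    # IUPAC-aware scoring: two codes whose base sets intersect score as a match,
    # so ambiguity codes in 16S reads do not spuriously depress identity.
    letters = IUPAC_DNA
    m = substitution_matrices.Array(letters, dims=2)
    for a in letters:
        for b in letters:
            hit = not IUPAC_SETS[a].isdisjoint(IUPAC_SETS[b])
            m[a, b] = params.match if hit else params.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # end-gap-free: terminal gaps cost nothing and their columns are excluded
    aligner.end_gap_score = 0.0
    return aligner


def pairwise_identity(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Fraction of identical columns in the end-gap-free global alignment.

    Columns lying in a terminal-gap run of either sequence are excluded from
    the denominator; internal gap columns count as mismatches. Positions
    whose IUPAC base sets intersect count as matches. Symmetric, in [0, 1].
    """
    if not a or not b:
        raise ParameterError("sequences must be non-empty")
    params = params or AlignmentParams()
    # canonical argument order: among co-optimal alignments the aligner's
    # choice depends on which sequence is the target, which would break
    # symmetry of the reported identity
    if b < a:
        a, b = b, a
    aln = _aligner(params).align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    L = len(ra)
    lead = max(len(ra) - len(ra.lstrip("-")), len(rb) - len(rb.lstrip("-")))
    trail = max(len(ra) - len(ra.rstrip("-")), len(rb) - len(rb.rstrip("-")))
    ncols = L - lead - trail
    if ncols <= 0:
        return 0.0
    matches = 0
    for i in range(lead, L - trail):
        ca, cb = ra[i], rb[i]
        if ca != "-" and cb != "-" and not IUPAC_SETS[ca].isdisjoint(IUPAC_SETS[cb]):
            matches += 1
    return matches / ncols


def identity_matrix(
    seqs: list[SequenceRecord], params: AlignmentParams | None = None
) -> IdentityMatrix:
    """All-pairs identity; symmetric by construction, diagonal exactly 1."""
    ids = [s.id for s in seqs]
    if len(ids) != len(set(ids)):
        raise ParameterError("duplicate sequence ids")
    if len(seqs) < 2:
        raise ParameterError("need at least 2 sequences")
    n = len(seqs)
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(
                seqs[i].residues, seqs[j].residues, params
            )
    return IdentityMatrix(ids=ids, values=m)


def cluster_otus(
    m: IdentityMatrix,
    threshold: float,
    lengths: dict[str, int] | None = None,
) -> OTUPartition:
    """Complete-linkage clustering on 1 - identity, cut at 1 - threshold.

    The complete-linkage cut guarantees every within-cluster pair has
    identity >= threshold. The representative of each cluster is its longest
    member (if ``lengths`` is given), ties broken by lexicographic id.
    Clusters are ordered by first appearance of a member in the input.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    n = len(m.ids)
    if n == 1:
        return OTUPartition(threshold, [list(m.ids)], [m.ids[0]])
    dist = np.clip(1.0 - m.values, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="complete")
    # tiny epsilon so identity == threshold (distance == cut) merges despite
    # floating-point representation of the threshold
    labels = fcluster(Z, t=(1.0 - threshold) + 1e-9, criterion="distance")
    groups: dict[int, list[str]] = {}
    order: list[int] = []
    for sid, lab in zip(m.ids, labels):
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(sid)
    clusters = [sorted(groups[lab]) for lab in order]
    reps = []
    for members in clusters:
        if lengths:
            rep = min(members, key=lambda s: (-lengths[s], s))
        else:
            rep = min(members)
        reps.append(rep)
    return OTUPartition(threshold, clusters, reps)


def dereplicate(p: OTUPartition) -> tuple[list[str], int]:
    """Representatives and duplicate count from a 100%-identity partition."""
    if p.threshold != 1.0:
        raise ParameterError("dereplicate requires a partition built at threshold 1.0")
    total = sum(len(c) for c in p.clusters)
    return list(p.representatives), total - p.n_otus


def composition_summary(
    p: OTUPartition, genus_of: dict[str, str]
) -> pd.DataFrame:
    """Per-genus OTU counts and percentages (one-decimal, half-up).

    An OTU is attributed to the genus of its representative.
    """
    missing = [r for r in p.representatives if r not in genus_of]
    if missing:
        raise ParameterError(f"missing genus label for: {', '.join(sorted(missing))}")
    counts: dict[str, int] = {}
    for rep in p.representatives:
        g = genus_of[rep]
        counts[g] = counts.get(g, 0) + 1
    rows = [
        {"genus": g, "otus": c, "percent": percent(c, p.n_otus)}
        for g, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["genus", "otus", "percent"])
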