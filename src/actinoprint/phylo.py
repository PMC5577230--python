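"""Distance-based phylogenetics: p-distance, Jukes-Cantor, neighbor joining,
column-bootstrap support, and six-frame translation of biosynthetic fragments.

Neighbor joining follows the classical Saitou-Nei/Studier-Keppler Q-criterion
with deterministic tie-breaking (smallest active index pair) and negative
branch lengths clamped to zero (deficit logged). Trees are held as scikit-bio
``TreeNode`` objects; the NJ root is the final trifurcation of an unrooted
tree.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from skbio import TreeNode

from .dna import DNA_BASES, revcomp
from .io import SequenceRecord
from .util import ParameterError

logger = logging.getLogger(__name__)

_DNA_COMPARABLE = set(DNA_BASES)
_PROTEIN_COMPARABLE = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    model: str  # {"p-distance", "jukes-cantor", "protein-p"}


def p_distance(a: str, b: str, alphabet: str = "dna") -> float:
    """Proportion of mismatches over comparable columns of two aligned rows.

    Columns with a gap or an ambiguity code in either row are excluded.
    """
    if len(a) != len(b):
        raise ParameterError("sequences must be aligned to equal length")
    comparable = _DNA_COMPARABLE if alphabet == "dna" else _PROTEIN_COMPARABLE
    n = mism = 0
    for ca, cb in zip(a, b):
        if ca in comparable and cb in comparable:
            n += 1
            if ca != cb:
                mism += 1
    if n == 0:
        raise ParameterError("no comparable columns between sequences")
    return mism / n


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3); saturates at p >= 0.75."""
    if not 0.0 <= p < 0.75:
        raise ParameterError(f"p-distance {p} outside [0, 0.75): JC saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _encode(rows: list[str]) -> np.ndarray:
    return np.vstack([np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in rows])


def _comparable_codes(alphabet: str) -> np.ndarray:
    comparable = _DNA_COMPARABLE if alphabet == "dna" else _PROTEIN_COMPARABLE
    return np.frombuffer("".join(sorted(comparable)).encode("ascii"), dtype=np.uint8)


def _pairwise_p_arr(arr: np.ndarray, codes: np.ndarray) -> np.ndarray:
    comp = np.isin(arr, codes)
    both = comp[:, None, :] & comp[None, :, :]
    mism = (arr[:, None, :] != arr[None, :, :]) & both
    n_comp = both.sum(axis=-1)
    off_diag = ~np.eye(arr.shape[0], dtype=bool)
    if np.any(n_comp[off_diag] == 0):
        raise ParameterError("a sequence pair shares no comparable columns")
    p = np.zeros_like(n_comp, dtype=float)
    np.divide(mism.sum(axis=-1), n_comp, out=p, where=n_comp > 0)
    np.fill_diagonal(p, 0.0)
    return p


def _pairwise_p(rows: list[str], alphabet: str) -> np.ndarray:
    """Vectorized all-pairs p-distance over comparable columns."""
    return _pairwise_p_arr(_encode(rows), _comparable_codes(alphabet))


def distance_matrix(
    seqs: list[SequenceRecord], model: str = "p-distance", alphabet: str = "dna"
) -> DistanceMatrix:
    """All-pairs distances from an alignment under the requested model."""
    if model not in {"p-distance", "jukes-cantor", "protein-p"}:
        raise ParameterError(f"unknown model {model!r}")
    if model == "protein-p":
        alphabet = "protein"
    lengths = {len(s.residues) for s in seqs}
    if len(lengths) > 1:
        raise ParameterError("alignment rows differ in length")
    p = _pairwise_p([s.residues for s in seqs], alphabet)
    if model == "jukes-cantor":
        if np.any(p >= 0.75):
            raise ParameterError("p-distance >= 0.75: Jukes-Cantor saturated")
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        np.fill_diagonal(d, 0.0)
    else:
        d = p
    return DistanceMatrix([s.id for s in seqs], d, model)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with deterministic tie-breaks.

    Joins minimize the Q-criterion; among equal-Q pairs the smallest active
    index pair is taken. Negative branch-length estimates are clamped to 0
    and the deficit logged. Returns an unrooted tree as a ``TreeNode`` whose
    root trifurcates (n >= 3 required).
    """
    n = len(dm.ids)
    if n < 3:
        raise ParameterError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ParameterError("distance matrix contains non-finite entries")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("clamped negative branch length %.3g to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf
        # smallest Q; ties resolved toward the smallest (i, j) index pair
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12)
        i, j = map(int, cand[0])
        dij = d[i, j]
        li = clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(dij - li if li > 0 else dij)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    return TreeNode(children=[a, b, c])


def _bipartitions(tree: TreeNode, ref: str) -> set[frozenset[str]]:
    """Internal-edge bipartitions, each encoded as the side excluding *ref*."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if len(side) >= 2 and len(all_tips) - len(side) >= 2:
            parts.add(side)
    return parts


def bootstrap_support(
    alignment: list[SequenceRecord],
    n_reps: int,
    rng_seed: int,
    model: str = "p-distance",
) -> TreeNode:
    """NJ tree with internal-node bootstrap supports in [0, 100].

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of an internal edge is the percentage of replicate NJ trees
    containing the same leaf bipartition. Deterministic given the seed.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    ncols = len(alignment[0].residues)
    if any(len(s.residues) != ncols for s in alignment):
        raise ParameterError("alignment rows differ in length")
    if ncols < 2:
        raise ParameterError("alignment must have at least 2 columns")
    tree = neighbor_joining(distance_matrix(alignment, model))
    ref = alignment[0].id
    ids = [s.id for s in alignment]
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(rng_seed)
    arr = _encode([s.residues for s in alignment])
    codes = _comparable_codes("protein" if model == "protein-p" else "dna")
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        p = _pairwise_p_arr(arr[:, cols], codes)
        if model == "jukes-cantor":
            p = -0.75 * np.log1p(-4.0 * np.minimum(p, 0.7499) / 3.0)
            np.fill_diagonal(p, 0.0)
        rep_tree = neighbor_joining(DistanceMatrix(ids, p, model))
        for part in _bipartitions(rep_tree, ref):
            counts[part] = counts.get(part, 0) + 1
    all_tips = frozenset(s.id for s in alignment)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        node.support = 100.0 * counts.get(side, 0) / n_reps
        node.name = f"{node.support:.0f}"
    return tree


_FRAME_ORDER = ("+1", "+2", "+3", "-1", "-2", "-3")


def _longest_stop_free(aa: str) -> int:
    return max((len(run) for run in aa.split("*")), default=0)


def translate_fragment(nt: str, min_quality: int = 10) -> str:
    """Translate a fragment in the frame with the longest stop-free stretch.

    All six frames are translated with the standard code; ties go to the
    first frame in the order +1, +2, +3, -1, -2, -3. If no frame offers at
    least ``min_quality`` consecutive stop-free residues a warning is issued
    and the best frame is returned anyway.
    """
    if len(nt) < 3:
        raise ParameterError("fragment shorter than one codon")
    rc = revcomp(nt)
    best_aa, best_len = "", -1
    for frame in _FRAME_ORDER:
        src = nt if frame[0] == "+" else rc
        off = int(frame[1]) - 1
        sub = src[off:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate())
        run = _longest_stop_free(aa)
        if run > best_len:
            best_aa, best_len = aa, run
    if best_len < min_quality:
        warnings.warn(
            f"no reading frame with >= {min_quality} stop-free residues; "
            "returning best frame anyway",
            stacklevel=2,
        )
    return best_aa
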