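"""Restriction fingerprinting of amplicons with a simulated gel model.

Amplicons are digested in silico with 4-base cutters (AluI AG^CT, HaeIII
GG^CC by default); fragments are rendered into a "lane" by a densitometry
model in which band intensity is proportional to total fragment mass (bp),
co-migrating fragments merge within the gel's resolution, and only bands
whose area exceeds 5% of the whole lane area are scored (strictly greater
than, measured against the pre-filter lane total). Scored bands across lanes
are pooled into size bins with the same tolerance rule, producing the binary
isolates x band matrix that downstream Jaccard/UPGMA clustering consumes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .dna import validate_dna
from .util import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class Enzyme:
    """A restriction enzyme: concrete recognition site and cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        validate_dna(self.site, strict=True, name=f"{self.name} site")
        if len(self.site) < 4:
            raise ParameterError(f"{self.name}: recognition site shorter than 4 bp")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ParameterError(f"{self.name}: cut offset outside site")


@dataclass
class GelModel:
    """Electrophoresis/densitometry parameters.

    Fragments below ``min_detectable`` bp run off the gel; two bands
    co-migrate when their sizes differ by at most
    ``max(resolution_bp, resolution_frac * larger_size)``.
    """

    min_detectable: int = 50
    resolution_bp: float = 5.0
    resolution_frac: float = 0.02

    def comigrate(self, smaller: float, larger: float) -> bool:
        tol = max(self.resolution_bp, self.resolution_frac * larger)
        return larger - smaller <= tol


@dataclass
class LaneProfile:
    """One simulated gel lane: (size bp, area fraction) bands, largest first."""

    isolate_id: str
    enzyme: str
    bands: list[tuple[float, float]] = field(default_factory=list)


def digest(seq: str, enzyme: Enzyme) -> list[int]:
    """Fragment lengths (5'->3') after cutting a linear molecule.

    Every position is scanned, so overlapping recognition sites each
    contribute a cut; fragment lengths always sum to the sequence length.
    """
    validate_dna(seq, name="sequence")
    site, off = enzyme.site, enzyme.cut_offset
    cuts = sorted(
        {
            i + off
            for i in range(len(seq) - len(site) + 1)
            if seq[i:i + len(site)] == site
        }
        - {0, len(seq)}
    )
    bounds = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _chain_groups(sizes_desc: list[float], gel: GelModel) -> list[list[int]]:
    """Single-linkage grouping of descending sizes under the gel tolerance."""
    groups: list[list[int]] = []
    for idx, size in enumerate(sizes_desc):
        if groups and gel.comigrate(size, sizes_desc[groups[-1][-1]]):
            groups[-1].append(idx)
        else:
            groups.append([idx])
    return groups


def lane_from_fragments(
    fragments: list[int],
    gel: GelModel | None = None,
    isolate_id: str = "",
    enzyme: str = "",
) -> LaneProfile:
    """Densitometry model: fragments -> detected, merged, normalized bands.

    Band area is proportional to the total bp of its fragments (mass-scaled
    staining); merged band size is the mass-weighted mean of its fragments.
    Areas are normalized to the whole-lane (post-detection) total. A lane
    whose fragments all run off the gel is returned empty, with a log note.
    """
    if not fragments:
        raise ParameterError("need at least one fragment")
    gel = gel or GelModel()
    visible = sorted((f for f in fragments if f >= gel.min_detectable), reverse=True)
    if not visible:
        logger.info("lane %s/%s: all fragments below detection", isolate_id, enzyme)
        return LaneProfile(isolate_id, enzyme, [])
    total = float(sum(visible))
    bands = []
    for group in _chain_groups([float(v) for v in visible], gel):
        mass = float(sum(visible[i] for i in group))
        size = sum(visible[i] * visible[i] for i in group) / mass
        bands.append((size, mass / total))
    return LaneProfile(isolate_id, enzyme, bands)


def apply_area_filter(lane: LaneProfile, min_fraction: float = 0.05) -> LaneProfile:
    """Score only bands whose area fraction exceeds ``min_fraction``.

    The comparison is strict (area > 5% of the whole lane) and fractions are
    measured against the pre-filter lane total; retained bands keep their
    original fractions, so the operation is idempotent.
    """
    kept = [(s, a) for s, a in lane.bands if a > min_fraction]
    return LaneProfile(lane.isolate_id, lane.enzyme, kept)


def band_matrix(lanes: list[LaneProfile], gel: GelModel | None = None) -> pd.DataFrame:
    """Binary isolates x band-size-bin matrix from scored lanes.

    All retained band sizes are pooled, sorted descending, and binned by
    single-linkage under the co-migration tolerance, so a band shared by two
    lanes lands in one column. Column labels are the bin mean sizes,
    strictly decreasing; every column has at least one positive entry.
    """
    gel = gel or GelModel()
    enzymes = {lane.enzyme for lane in lanes}
    if len(enzymes) > 1:
        raise ParameterError(f"lanes from multiple enzymes: {sorted(enzymes)}")
    ids = [lane.isolate_id for lane in lanes]
    if len(ids) != len(set(ids)):
        raise ParameterError("duplicate lane ids")
    pooled = sorted(
        ((size, lane.isolate_id) for lane in lanes for size, _ in lane.bands),
        key=lambda t: -t[0],
    )
    if not pooled:
        return pd.DataFrame(index=ids, dtype=int)
    sizes = [s for s, _ in pooled]
    groups = _chain_groups(sizes, gel)
    columns = []
    matrix = pd.DataFrame(0, index=ids, columns=range(len(groups)))
    for col, group in enumerate(groups):
        rep = sum(sizes[i] for i in group) / len(group)
        columns.append(round(rep, 1))
        for i in group:
            matrix.loc[pooled[i][1], col] = 1
    matrix.columns = columns
    return matrix


def combine_matrices(
    ma: pd.DataFrame, mb: pd.DataFrame, names: tuple[str, str] = ("A", "B")
) -> pd.DataFrame:
    """Column-wise concatenation of two band matrices over the same lanes.

    Columns are tagged with the enzyme name so bins from different digests
    never collide.
    """
    if list(ma.index) != list(mb.index):
        raise ParameterError("band matrices cover different isolates")
    a = ma.copy()
    b = mb.copy()
    a.columns = [f"{names[0]}:{c}" for c in ma.columns]
    b.columns = [f"{names[1]}:{c}" for c in mb.columns]
    return pd.concat([a, b], axis=1)
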