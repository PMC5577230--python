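"""In-silico PCR with degenerate primers for biosynthetic-gene screening.

The targets are the adenylation domain of nonribosomal peptide synthetases
(NRPS, 480 bp product) and the ketosynthase-alpha domain of type II
polyketide synthases (PKS-II, 350 bp product), detected with IUPAC-degenerate
primer pairs. A primer binds where every position is compatible (base sets
intersect) up to a configurable mismatch budget; an isolate is called
positive when a forward/reverse site pairing yields a product whose length
falls inside the expected-size window. Amplicon lengths are measured 5'-end
to 5'-end inclusive of both primer footprints, matching how PCR product
sizes are conventionally stated.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .dna import DNA_BASES, IUPAC_SETS, revcomp, validate_dna
from .util import ParameterError, percent


@dataclass
class PrimerPair:
    """A degenerate primer pair with its expected product size."""

    locus: str
    forward: str
    reverse: str
    expected_size: int
    size_tolerance: float = 0.2  # fraction of expected_size

    def __post_init__(self) -> None:
        validate_dna(self.forward, name=f"{self.locus} forward primer")
        validate_dna(self.reverse, name=f"{self.locus} reverse primer")
        if self.expected_size <= len(self.forward) + len(self.reverse):
            raise ParameterError(
                f"{self.locus}: expected_size must exceed total primer length"
            )

    def size_window(self) -> tuple[float, float]:
        lo = self.expected_size * (1.0 - self.size_tolerance)
        hi = self.expected_size * (1.0 + self.size_tolerance)
        return lo, hi


@dataclass
class Amplicon:
    start: int   # 0-based, inclusive; plus-strand coordinates
    end: int     # 0-based, exclusive
    length: int
    sequence: str


@dataclass
class AmpliconCall:
    """Outcome of in-silico PCR for one template x one locus."""

    locus: str
    positive: bool
    amplicons: list[Amplicon] = field(default_factory=list)
    isolate_id: str | None = None


def iupac_match(pattern_char: str, base: str) -> bool:
    """True iff a concrete base lies in the expansion of an IUPAC code."""
    if pattern_char not in IUPAC_SETS:
        raise ParameterError(f"illegal IUPAC code {pattern_char!r}")
    if base not in DNA_BASES:
        raise ParameterError(f"base must be one of ACGT, got {base!r}")
    return base in IUPAC_SETS[pattern_char]


def _compatible(pattern_char: str, template_char: str) -> bool:
    # template may itself carry ambiguity codes; compatibility is base-set
    # intersection
    return not IUPAC_SETS[pattern_char].isdisjoint(IUPAC_SETS[template_char])


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        bases = sorted(IUPAC_SETS[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def _scan_one_strand(template: str, pattern: str, max_mismatch: int) -> list[int]:
    k = len(pattern)
    if k > len(template):
        return []
    if max_mismatch == 0 and all(c in DNA_BASES for c in template):
        return [m.start() for m in _pattern_regex(pattern).finditer(template)]
    hits = []
    for pos in range(len(template) - k + 1):
        mism = 0
        for pc, tc in zip(pattern, template[pos:pos + k]):
            if not _compatible(pc, tc):
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(pos)
    return hits


def find_binding_sites(
    template: str, primer: str, max_mismatch: int = 0
) -> list[tuple[int, str]]:
    """Positions where a degenerate primer binds either strand.

    The plus strand is scanned for the primer itself (strand ``"+"``) and for
    its reverse complement (strand ``"-"``); positions are 0-based at the
    5'-most template base of the site window. A site tolerates up to
    ``max_mismatch`` incompatible positions.
    """
    validate_dna(template, name="template")
    validate_dna(primer, name="primer")
    sites = [(p, "+") for p in _scan_one_strand(template, primer, max_mismatch)]
    sites += [(p, "-") for p in _scan_one_strand(template, revcomp(primer), max_mismatch)]
    return sorted(sites)


def insilico_pcr(
    template: str, pair: PrimerPair, max_mismatch: int = 0
) -> AmpliconCall:
    """All products the primer pair would amplify from a linear template.

    A product needs the forward primer annealing on one strand and the
    reverse primer on the other, pointing toward each other. Both template
    orientations are considered; coordinates are reported on the plus strand
    and the call is positive when any product length falls within
    ``expected_size * (1 +/- size_tolerance)``.
    """
    validate_dna(template, name="template")
    lf, lr = len(pair.forward), len(pair.reverse)
    found: dict[tuple[int, int], Amplicon] = {}

    def orientation(seq: str, flip: bool) -> None:
        fwd_sites = _scan_one_strand(seq, pair.forward, max_mismatch)
        rev_sites = _scan_one_strand(seq, revcomp(pair.reverse), max_mismatch)
        L = len(seq)
        for f in fwd_sites:
            for r in rev_sites:
                if r < f + lf:
                    continue  # primers must not overlap
                start, end = f, r + lr
                if flip:
                    start, end = L - end, L - start
                found[(start, end)] = Amplicon(
                    start=start,
                    end=end,
                    length=end - start,
                    sequence=template[start:end],
                )

    orientation(template, flip=False)
    orientation(revcomp(template), flip=True)
    amplicons = [found[k] for k in sorted(found)]
    lo, hi = pair.size_window()
    positive = any(lo <= a.length <= hi for a in amplicons)
    return AmpliconCall(locus=pair.locus, positive=positive, amplicons=amplicons)


def screen_isolates(isolates, pairs: list[PrimerPair], max_mismatch: int = 0) -> pd.DataFrame:
    """Boolean presence table (isolates x loci) from in-silico PCR.

    Every marker template carried by an isolate is screened against every
    primer pair; a locus is positive if any template yields a positive call.
    """
    ids = [iso.isolate_id for iso in isolates]
    if len(ids) != len(set(ids)):
        raise ParameterError("duplicate isolate ids")
    table = pd.DataFrame(False, index=ids, columns=[p.locus for p in pairs])
    for iso in isolates:
        templates = [t for seqs in iso.marker_templates.values() for t in seqs]
        for pair in pairs:
            table.loc[iso.isolate_id, pair.locus] = any(
                insilico_pcr(t, pair, max_mismatch).positive for t in templates
            )
    return table


def screen_summary(table: pd.DataFrame, genus_of: dict[str, str]) -> pd.DataFrame:
    """Overall and per-genus prevalence percentages of each locus.

    Reports, for the whole collection and per genus: isolate count, percent
    positive per locus, percent positive for at least one locus, and percent
    negative for all loci. Percentages follow the shared one-decimal
    half-up rule.
    """
    missing = [i for i in table.index if i not in genus_of]
    if missing:
        raise ParameterError(f"missing genus label for: {', '.join(sorted(missing))}")
    loci = list(table.columns)

    def summarize(sub: pd.DataFrame, label: str) -> dict:
        n = len(sub)
        row = {"group": label, "n": n}
        for locus in loci:
            row[f"{locus}_pct"] = percent(int(sub[locus].sum()), n)
        any_pos = int(sub.any(axis=1).sum())
        row["either_or_both_pct"] = percent(any_pos, n)
        row["neither_pct"] = percent(n - any_pos, n)
        return row

    rows = [summarize(table, "all")]
    genera = sorted({genus_of[i] for i in table.index})
    for g in genera:
        members = [i for i in table.index if genus_of[i] == g]
        rows.append(summarize(table.loc[members], g))
    return pd.DataFrame(rows)
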