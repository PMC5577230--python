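"""Synthetic actinobacterial communities with planted, testable structure.

The generator emulates the statistical shape of a cultivable-isolate
collection: a configurable number of genera (each a random 16S template,
far apart from the others), within-genus 16S variation from i.i.d. per-site
substitutions, biosynthetic marker loci built around real degenerate-primer
binding sites so in-silico PCR recovers products of the expected sizes
(480 bp NRPS, 350 bp PKS-II), and binary antibacterial-activity labels whose
probability depends on gene content. Everything is reproducible from one
seed; per-isolate random streams are derived by counter-based splitting so
earlier isolates never change when more are appended.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults
from .dna import random_dna, realize, revcomp, validate_dna
from .io import SequenceRecord, write_fasta
from .screen import PrimerPair, insilico_pcr
from .util import ConfigError, ParameterError

_TEMPLATE_STREAM = 1_000_003  # spawn-key offset separating template draws


@dataclass
class GenusSpec:
    name: str
    proportion: float
    template_id: str


@dataclass
class IsolateRecord:
    """One (synthetic) isolate and everything downstream stages consume."""

    isolate_id: str
    genus: str
    aerial_mycelium: bool
    sixteenS: str
    marker_templates: dict[str, list[str]] = field(default_factory=dict)
    activity: dict[str, bool] = field(default_factory=dict)


@dataclass
class CommunityConfig:
    """Parameters of one synthetic community; see module docstring.

    ``divergence_within_genus`` is the approximate *pairwise* substitution
    fraction between two isolates of one genus (each isolate is mutated from
    the genus template at half this rate);
    ``gene_prevalence`` maps genus -> (P(NRPS), P(PKS-II));
    ``activity_model`` maps gene-content category ("both"/"one"/"none") to
    the probability of antibacterial activity; ``insert_length_jitter``
    widens the inter-primer insert by U{-j..j} bp around the value that
    makes the amplicon exactly the expected size.
    """

    n_isolates: int = 66
    genus_spec: list[GenusSpec] = field(default_factory=list)
    templates: dict[str, str] = field(default_factory=dict)
    divergence_within_genus: float = 0.004
    gene_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(defaults.GENE_PREVALENCE)
    )
    primer_pairs: dict[str, PrimerPair] = field(
        default_factory=lambda: dict(defaults.PRIMER_PAIRS)
    )
    insert_length_jitter: int = 0
    activity_model: dict[str, float] = field(
        default_factory=lambda: dict(defaults.ACTIVITY_MODEL)
    )
    test_strains: list[str] = field(default_factory=lambda: list(defaults.TEST_STRAINS))
    aerial_mycelium_p: float = defaults.AERIAL_MYCELIUM_P
    extra_strain_hit_p: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_isolates < 1:
            raise ConfigError("n_isolates must be >= 1")
        if not self.genus_spec:
            raise ConfigError("genus_spec is empty")
        total = sum(g.proportion for g in self.genus_spec)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"genus proportions sum to {total}, not 1")
        if not 0.0 <= self.divergence_within_genus <= 0.25:
            raise ConfigError("divergence_within_genus must be in [0, 0.25]")
        for g in self.genus_spec:
            if g.template_id not in self.templates:
                raise ConfigError(f"missing 16S template {g.template_id!r}")
            validate_dna(self.templates[g.template_id], name=g.template_id)
            pn, pk = self.gene_prevalence.get(g.name, (0.0, 0.0))
            if not (0.0 <= pn <= 1.0 and 0.0 <= pk <= 1.0):
                raise ConfigError(f"gene prevalence for {g.name} outside [0, 1]")
        for cat, p in self.activity_model.items():
            if cat not in {"both", "one", "none"} or not 0.0 <= p <= 1.0:
                raise ConfigError(f"bad activity model entry {cat}={p}")


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def mutate_sequence(template: str, divergence: float, rng_seed: int | np.random.Generator) -> str:
    """Substitute each site independently with probability ``divergence``.

    Substitutions are uniform over the three alternative bases and never
    silent, so expected identity to the template is exactly 1 - divergence.
    Length is preserved (no indels); deterministic given the seed.
    """
    if not 0.0 <= divergence <= 0.25:
        raise ParameterError("divergence must be in [0, 0.25]")
    validate_dna(template, strict=True, name="template")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    seq = list(template)
    hits = np.flatnonzero(rng.random(len(seq)) < divergence)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(3)]
    return "".join(seq)


def plant_marker_locus(
    insert_length: int,
    primer_forward: str,
    primer_reverse: str,
    rng_seed: int,
    flank: int = 60,
) -> str:
    """A template that in-silico PCR amplifies to exactly one product.

    Layout: random flank + a concrete realization of the forward primer +
    random insert + reverse-complement of a concrete realization of the
    reverse primer + random flank. The product length is
    ``len(forward) + insert_length + len(reverse)``. The construction is
    verified against the primer pair and re-sampled (deterministically) in
    the vanishingly rare event a spurious binding site arises.
    """
    if insert_length < 0:
        raise ParameterError("insert_length must be >= 0")
    if not primer_forward or not primer_reverse:
        raise ParameterError("primers must be non-empty")
    expected = len(primer_forward) + insert_length + len(primer_reverse)
    pair = PrimerPair(
        locus="synthetic",
        forward=primer_forward,
        reverse=primer_reverse,
        expected_size=max(expected, len(primer_forward) + len(primer_reverse) + 1),
        size_tolerance=0.0,
    ) if expected > len(primer_forward) + len(primer_reverse) else None
    for attempt in range(25):
        rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(attempt,)))
        core = (
            realize(primer_forward, rng)
            + random_dna(insert_length, rng)
            + revcomp(realize(primer_reverse, rng))
        )
        template = random_dna(flank, rng) + core + random_dna(flank, rng)
        if pair is None:
            return template  # zero insert: nothing to verify against a window
        call = insilico_pcr(template, pair)
        if len(call.amplicons) == 1 and call.amplicons[0].length == expected:
            return template
    raise RuntimeError("could not construct a clean marker locus")  # pragma: no cover


def _largest_remainder(n: int, proportions: list[float]) -> list[int]:
    """Apportion n among proportions; ties broken by position order."""
    raw = [p * n for p in proportions]
    counts = [math.floor(x) for x in raw]
    short = n - sum(counts)
    by_remainder = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in by_remainder[:short]:
        counts[i] += 1
    return counts


def generate_community(config: CommunityConfig) -> list[IsolateRecord]:
    """Draw a full isolate collection from the configured model.

    Genus counts follow largest-remainder apportionment of the configured
    proportions. Each isolate's 16S is an independent mutant of its genus
    template at rate ``divergence_within_genus / 2``, so the *pairwise*
    divergence between genus mates is approximately
    ``divergence_within_genus`` - the quantity OTU thresholds act on.
    Each isolate further gets
    Bernoulli gene carriage with planted marker loci, and activity labels
    drawn from the gene-content-conditional activity model (an active
    isolate inhibits one uniformly chosen test strain plus each other strain
    independently). Byte-identical output for identical config and seed.
    """
    config.validate()
    counts = _largest_remainder(
        config.n_isolates, [g.proportion for g in config.genus_spec]
    )
    width = max(3, len(str(config.n_isolates)))
    records: list[IsolateRecord] = []
    idx = 0
    for spec, count in zip(config.genus_spec, counts):
        template = config.templates[spec.template_id]
        pn, pk = config.gene_prevalence.get(spec.name, (0.0, 0.0))
        for _ in range(count):
            rng = _rng_for(config.seed, idx)
            isolate_id = f"SYN{idx + 1:0{width}d}"
            sixteenS = mutate_sequence(
                template, config.divergence_within_genus / 2.0, rng
            )
            aerial = bool(rng.random() < config.aerial_mycelium_p)
            markers: dict[str, list[str]] = {}
            carried = 0
            for locus, prob in (("NRPS", pn), ("PKS-II", pk)):
                if locus not in config.primer_pairs:
                    continue
                pair = config.primer_pairs[locus]
                if rng.random() < prob:
                    carried += 1
                    base_insert = pair.expected_size - len(pair.forward) - len(pair.reverse)
                    j = config.insert_length_jitter
                    insert = base_insert + (int(rng.integers(-j, j + 1)) if j else 0)
                    markers[locus] = [
                        plant_marker_locus(
                            insert,
                            pair.forward,
                            pair.reverse,
                            rng_seed=int(rng.integers(2**31)),
                        )
                    ]
            category = "both" if carried >= 2 else ("one" if carried == 1 else "none")
            activity = {s: False for s in config.test_strains}
            if config.test_strains and rng.random() < config.activity_model[category]:
                primary = config.test_strains[rng.integers(len(config.test_strains))]
                for strain in config.test_strains:
                    hit = strain == primary or rng.random() < config.extra_strain_hit_p
                    activity[strain] = bool(hit)
            records.append(
                IsolateRecord(
                    isolate_id=isolate_id,
                    genus=spec.name,
                    aerial_mycelium=aerial,
                    sixteenS=sixteenS,
                    marker_templates=markers,
                    activity=activity,
                )
            )
            idx += 1
    return records


def make_templates(
    n: int, length: int, seed: int, min_divergence: float = 0.05
) -> dict[str, str]:
    """Independent random 16S templates, pairwise divergence >= min_divergence.

    Uniform random sequences differ at ~75% of sites, so the divergence
    floor is essentially always satisfied on the first draw; it is verified
    anyway and violating draws are rejected deterministically.
    """
    templates: dict[str, str] = {}
    stream = 0
    while len(templates) < n:
        rng = _rng_for(seed, _TEMPLATE_STREAM + stream)
        stream += 1
        cand = random_dna(length, rng)
        ok = all(
            sum(a != b for a, b in zip(cand, t)) / length >= min_divergence
            for t in templates.values()
        )
        if ok:
            templates[f"T{len(templates) + 1:02d}"] = cand
    return templates


def default_config(seed: int = 0, template_length: int = 1300) -> CommunityConfig:
    """The default 66-isolate, 7-genus community configuration."""
    genera = list(defaults.GENUS_COUNTS_66)
    templates = make_templates(len(genera), template_length, seed)
    total = sum(defaults.GENUS_COUNTS_66.values())
    spec = [
        GenusSpec(name=g, proportion=defaults.GENUS_COUNTS_66[g] / total,
                  template_id=tid)
        for g, tid in zip(genera, templates)
    ]
    return CommunityConfig(n_isolates=total, genus_spec=spec, templates=templates, seed=seed)


def write_community(records: list[IsolateRecord], outdir: str | Path) -> None:
    """Write 16S FASTA, marker-template FASTA and a metadata TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [SequenceRecord(r.isolate_id, r.genus, r.sixteenS) for r in records],
        outdir / "sixteenS.fasta",
    )
    marker_records = [
        SequenceRecord(f"{r.isolate_id}|{locus}|{k}", "", seq)
        for r in records
        for locus, seqs in sorted(r.marker_templates.items())
        for k, seq in enumerate(seqs)
    ]
    if marker_records:
        write_fasta(marker_records, outdir / "markers.fasta")
    strains = sorted({s for r in records for s in r.activity})
    rows = []
    for r in records:
        row = {
            "isolate_id": r.isolate_id,
            "genus": r.genus,
            "aerial_mycelium": int(r.aerial_mycelium),
        }
        row.update({s: int(r.activity.get(s, False)) for s in strains})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
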