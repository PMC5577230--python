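"""End-to-end orchestration: simulate -> OTU -> tree -> screen -> fingerprint
-> cluster -> network -> report.

`run_pipeline` executes the stages in dependency order against one seeded
configuration, writes every intermediate as plain text (TSV / FASTA /
Newick / GraphML) into a run directory, and renders a summary report. Runs
are deterministic: identical config and seed give byte-identical outputs
(no timestamps are written), and every artifact-bearing run records the
config hash and seed in ``run_info.json``.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import defaults
from .cluster import fingerprint_report
from .fingerprint import (
    GelModel,
    apply_area_filter,
    band_matrix,
    combine_matrices,
    digest,
    lane_from_fragments,
)
from .io import SequenceRecord, read_fasta, write_matrix, write_newick
from .network import build_network, crosstab_activity_genes, export_graph, activity_summary
from .otu import cluster_otus, composition_summary, dereplicate, identity_matrix
from .phylo import bootstrap_support
from .screen import insilico_pcr, screen_isolates, screen_summary
from .synthetic import IsolateRecord, default_config, generate_community, write_community
from .util import ActinoprintError, ConfigError, percent

logger = logging.getLogger(__name__)

_ALL_STAGES = ("otu", "tree", "screen", "fingerprint", "cluster", "network")


@dataclass
class PipelineConfig:
    """Every numeric setting of the workflow, in one place."""

    seed: int = 7
    n_isolates: int = 66
    template_length: int = 1300
    divergence_within_genus: float = 0.004
    otu_thresholds: tuple[float, ...] = defaults.OTU_THRESHOLDS
    composition_threshold: float = 0.99
    bootstrap_reps: int = defaults.BOOTSTRAP_REPLICATES
    tree_model: str = "p-distance"
    min_band_area: float = defaults.MIN_BAND_AREA
    similarity_cut: float = defaults.SIMILARITY_CUT
    stages: tuple[str, ...] = _ALL_STAGES
    input_fasta: str | None = None      # skip simulation, read 16S from file
    input_metadata: str | None = None   # TSV with isolate_id, genus columns

    def validate(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        for t in self.otu_thresholds:
            if not 0 < t <= 1:
                raise ConfigError(f"OTU threshold {t} outside (0, 1]")
        if not 0 <= self.similarity_cut <= 1:
            raise ConfigError("similarity_cut outside [0, 1]")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")
        for path in (self.input_fasta, self.input_metadata):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input path not found: {path}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        })
        cfg.validate()
        return cfg


def _simulate_or_ingest(config: PipelineConfig, outdir: Path) -> list[IsolateRecord]:
    if config.input_fasta is not None:
        seqs = read_fasta(config.input_fasta)
        genus = {}
        if config.input_metadata:
            meta = pd.read_csv(config.input_metadata, sep="\t").set_index("isolate_id")
            genus = meta["genus"].to_dict()
        return [
            IsolateRecord(
                isolate_id=s.id,
                genus=genus.get(s.id, "unknown"),
                aerial_mycelium=True,
                sixteenS=s.residues,
            )
            for s in seqs
        ]
    cc = default_config(config.seed, config.template_length)
    cc.n_isolates = config.n_isolates
    cc.divergence_within_genus = config.divergence_within_genus
    records = generate_community(cc)
    write_community(records, outdir / "community")
    return records


def _stage_otu(records, config, outdir, results) -> None:
    seqs = [SequenceRecord(r.isolate_id, "", r.sixteenS) for r in records]
    m = identity_matrix(seqs)
    lengths = {r.isolate_id: len(r.sixteenS) for r in records}
    genus_of = {r.isolate_id: r.genus for r in records}
    counts = {}
    for t in config.otu_thresholds:
        p = cluster_otus(m, t, lengths)
        counts[t] = p.n_otus
        rows = [
            {"isolate_id": sid, "otu": k + 1, "representative": p.representatives[k]}
            for k, members in enumerate(p.clusters)
            for sid in members
        ]
        pd.DataFrame(rows).to_csv(
            outdir / f"otu_membership_{t:.2f}.tsv", sep="\t", index=False
        )
        if t == 1.0:
            _, dup = dereplicate(p)
            results["duplicates"] = dup
        if t == config.composition_threshold:
            comp = composition_summary(p, genus_of)
            comp.to_csv(outdir / "otu_composition.tsv", sep="\t", index=False)
            results["composition"] = comp
    results["otu_counts"] = counts


def _stage_tree(records, config, outdir, results) -> None:
    aln = [SequenceRecord(r.isolate_id, "", r.sixteenS) for r in records]
    tree = bootstrap_support(
        aln, n_reps=config.bootstrap_reps, rng_seed=config.seed,
        model=config.tree_model,
    )
    write_newick(tree, outdir / "sixteenS_nj.nwk")
    supports = [n.support for n in tree.non_tips(include_self=False)]
    results["tree"] = {
        "n_leaves": len(aln),
        "model": config.tree_model,
        "bootstrap_reps": config.bootstrap_reps,
        "mean_support": sum(supports) / len(supports) if supports else float("nan"),
    }


def _stage_screen(records, config, outdir, results) -> None:
    pairs = list(defaults.PRIMER_PAIRS.values())
    table = screen_isolates(records, pairs)
    write_matrix(table.astype(int), outdir / "gene_presence.tsv")
    genus_of = {r.isolate_id: r.genus for r in records}
    summary = screen_summary(table, genus_of)
    summary.to_csv(outdir / "screen_summary.tsv", sep="\t", index=False)
    results["gene_presence"] = table
    results["screen_summary"] = summary


def _stage_fingerprint(records, config, outdir, results) -> None:
    gel = GelModel()
    matrices: dict[str, pd.DataFrame] = {}
    for locus, pair in defaults.PRIMER_PAIRS.items():
        amplicons = {}
        for r in records:
            for template in r.marker_templates.get(locus, []):
                call = insilico_pcr(template, pair)
                if call.positive:
                    amplicons[r.isolate_id] = call.amplicons[0].sequence
                    break
        if not amplicons:
            continue
        per_enzyme = {}
        for name, enzyme in defaults.ENZYMES.items():
            lanes = [
                apply_area_filter(
                    lane_from_fragments(digest(seq, enzyme), gel, iso, name),
                    config.min_band_area,
                )
                for iso, seq in amplicons.items()
            ]
            bm = band_matrix(lanes, gel)
            write_matrix(bm, outdir / f"bands_{locus}_{name}.tsv")
            per_enzyme[name] = bm
        names = list(per_enzyme)
        combined = combine_matrices(
            per_enzyme[names[0]], per_enzyme[names[1]], (names[0], names[1])
        )
        write_matrix(combined, outdir / f"bands_{locus}_combined.tsv")
        matrices[locus] = combined
        for name, bm in per_enzyme.items():
            matrices[f"{locus}:{name}"] = bm
    results["band_matrices"] = matrices


def _stage_cluster(records, config, outdir, results) -> None:
    reports = {}
    for key, matrix in results.get("band_matrices", {}).items():
        nonempty = matrix.loc[matrix.any(axis=1)] if len(matrix.columns) else matrix
        if len(nonempty) < 1 or not len(matrix.columns):
            continue
        rep = fingerprint_report(nonempty, config.similarity_cut)
        reports[key] = rep
        if ":" not in key:
            rows = [
                {"isolate_id": iso, "group": k + 1}
                for k, group in enumerate(rep["groups"])
                for iso in group
            ]
            pd.DataFrame(rows).to_csv(
                outdir / f"fingerprint_groups_{key}.tsv", sep="\t", index=False
            )
    results["fingerprint_reports"] = reports


def _stage_network(records, config, outdir, results) -> None:
    strains = sorted({s for r in records for s in r.activity})
    activity = pd.DataFrame(
        [[r.activity.get(s, False) for s in strains] for r in records],
        index=[r.isolate_id for r in records],
        columns=strains,
    )
    write_matrix(activity.astype(int), outdir / "activity.tsv")
    results["activity_table"] = activity
    results["activity_summary"] = activity_summary(activity, defaults.GRAM_MAP)
    genes = results.get("gene_presence")
    if genes is None:
        return
    summary = crosstab_activity_genes(activity, genes)
    results["crosstab"] = summary
    graph = build_network(
        activity, genes, {r.isolate_id: r.genus for r in records}
    )
    export_graph(graph, outdir / "network_edges.tsv", "tsv")
    export_graph(graph, outdir / "network.graphml", "graphml")


def render_report(results: dict) -> str:
    """Markdown summary mirroring the workflow's headline statistics."""
    lines = ["# actinoprint run report", ""]
    n = results.get("n_isolates")
    if n is not None:
        lines.append(f"Isolates analysed: {n}")
        aerial = results.get("n_aerial")
        if aerial is not None:
            lines.append(
                f"With aerial mycelium: {aerial} ({percent(aerial, n)}%)"
            )
        lines.append("")
    if "otu_counts" in results:
        lines.append("## OTU clustering")
        for t, c in sorted(results["otu_counts"].items(), reverse=True):
            lines.append(f"- identity {t * 100:g}%: {c} OTUs")
        if "duplicates" in results:
            lines.append(f"- duplicates removed at 100%: {results['duplicates']}")
        comp = results.get("composition")
        if comp is not None:
            lines.append("")
            lines.append("Genus composition of OTUs:")
            for _, row in comp.iterrows():
                lines.append(f"- {row['genus']}: {row['otus']} OTUs ({row['percent']}%)")
        lines.append("")
    if "tree" in results:
        t = results["tree"]
        lines.append("## Phylogeny")
        lines.append(
            f"- NJ tree on {t['n_leaves']} leaves ({t['model']}), "
            f"{t['bootstrap_reps']} bootstrap replicates, "
            f"mean internal support {t['mean_support']:.1f}"
        )
        lines.append("")
    if "screen_summary" in results:
        lines.append("## Biosynthetic gene screen")
        overall = results["screen_summary"].iloc[0]
        for col in results["screen_summary"].columns:
            if col.endswith("_pct"):
                lines.append(f"- {col[:-4]}: {overall[col]}%")
        lines.append("")
    if "fingerprint_reports" in results:
        lines.append("## Restriction fingerprinting")
        for key, rep in sorted(results["fingerprint_reports"].items()):
            lines.append(
                f"- {key}: {rep['distinct_fragments']} distinct fragments, "
                f"{rep['n_groups']} groups at the similarity cut"
            )
        lines.append("")
    if "crosstab" in results:
        c = results["crosstab"]
        lines.append("## Activity x gene content")
        lines.append(f"- active isolates: {c.n_active}")
        lines.append(f"- both loci: {c.both} ({c.both_pct}%)")
        lines.append(f"- exactly one locus: {c.either} ({c.either_pct}%)")
        lines.append(f"- neither locus: {c.neither} ({c.neither_pct}%)")
        lines.append(f"- inactive gene carriers: {c.inactive_gene_positive}")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all enabled stages; returns the in-memory results dict.

    Any stage failure aborts the run with the failing stage named; outputs
    of completed stages are retained in the run directory.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_info.json").write_text(
        json.dumps({"config_hash": config.hash(), "seed": config.seed,
                    "config": dataclasses.asdict(config)},
                   sort_keys=True, default=str, indent=2)
        + "\n"
    )
    records = _simulate_or_ingest(config, outdir)
    results: dict = {
        "n_isolates": len(records),
        "n_aerial": sum(r.aerial_mycelium for r in records),
    }
    stage_fns = {
        "otu": _stage_otu,
        "tree": _stage_tree,
        "screen": _stage_screen,
        "fingerprint": _stage_fingerprint,
        "cluster": _stage_cluster,
        "network": _stage_network,
    }
    for stage in _ALL_STAGES:
        if stage not in config.stages:
            continue
        logger.info("stage %s starting", stage)
        try:
            stage_fns[stage](records, config, outdir, results)
        except ActinoprintError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "report.md").write_text(render_report(results))
    return results
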