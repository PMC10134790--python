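"""End-to-end orchestration: detect -> cluster -> profile -> subgroup ->
classify -> tree -> report.

Each stage is independently toggleable so any prefix of the pipeline can
run on its own; degenerate corpora (no large clusters, <3 cluster
representatives) skip the affected downstream stage with a logged reason
rather than failing.  With fixed inputs and seed the complete output set
is byte-identical across reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from .cluster import SequenceCluster, greedy_cluster
from .context import (DBSCAN_EPS, DBSCAN_MIN_SAMPLES, FREQ_FLOOR, MIN_MEMBERS,
                      ContextProfile, assign_subgroups, build_context_profile)
from .detect import SoloCall, classify_pair_topology, detect_solos
from .errors import ConfigError, ContractViolationError
from .genome import (AnnotatedGenome, CLASSES_COLUMNS, CLUSTERS_COLUMNS,
                     PROFILES_COLUMNS, SOLOS_COLUMNS, SUBGROUPS_COLUMNS,
                     ResultBundle, read_genome, write_outputs)
from .phylogeny import distance_matrix, neighbor_joining, write_annotated_newick

log = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1
ALL_STAGES = ("detect", "cluster", "profile", "subgroup", "classify",
              "tree", "report")


@dataclass(frozen=True)
class DistributionSummary:
    """Per-genome solo-count distribution with one-decimal percentages."""

    n_genomes: int
    n_solo_hits: int
    n_zero: int
    n_one: int
    n_multi: int
    pct_zero: float
    pct_one: float
    pct_multi: float


def _pct(count: int, total: int) -> float:
    """100*count/total, rounded half-up to one decimal."""
    if total == 0:
        return 0.0
    frac = Decimal(100 * count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_distribution(solo_counts: dict[str, int],
                           n_genomes: int) -> DistributionSummary:
    """Distribution of solo counts per genome.

    `solo_counts` maps genome id -> number of solos; genomes with zero
    solos may be omitted and are counted in the zero bin.
    """
    if len(solo_counts) > n_genomes:
        raise ContractViolationError(
            f"{len(solo_counts)} genomes with counts exceeds n_genomes={n_genomes}")
    n_one = sum(1 for c in solo_counts.values() if c == 1)
    n_multi = sum(1 for c in solo_counts.values() if c > 1)
    n_zero = n_genomes - n_one - n_multi
    return DistributionSummary(
        n_genomes=n_genomes,
        n_solo_hits=sum(solo_counts.values()),
        n_zero=n_zero, n_one=n_one, n_multi=n_multi,
        pct_zero=_pct(n_zero, n_genomes),
        pct_one=_pct(n_one, n_genomes),
        pct_multi=_pct(n_multi, n_genomes),
    )


@dataclass
class PipelineConfig:
    window: int = 4
    id_threshold: float = 0.80
    cov_threshold: float = 0.80
    profile_min_members: int = MIN_MEMBERS
    profile_freq_floor: float = FREQ_FLOOR
    embed_method: str = "pca"
    embed_seed: int = 0
    dbscan_eps: float = DBSCAN_EPS
    dbscan_min_samples: int = DBSCAN_MIN_SAMPLES
    reference_map: str | None = None
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        mapping = {
            ("profile", "window"): "window",
            ("profile", "min_members"): "profile_min_members",
            ("profile", "freq_floor"): "profile_freq_floor",
            ("embed", "method"): "embed_method",
            ("embed", "seed"): "embed_seed",
            ("dbscan", "eps"): "dbscan_eps",
            ("dbscan", "min_samples"): "dbscan_min_samples",
        }
        for key, val in raw.items():
            if isinstance(val, dict):
                for sub, v in val.items():
                    if (key, sub) not in mapping:
                        raise ConfigError(f"unknown config key {key}.{sub}")
                    flat[mapping[(key, sub)]] = v
            elif key in cls.__dataclass_fields__:
                flat[key] = tuple(val) if key == "stages" else val
            else:
                raise ConfigError(f"unknown config key {key}")
        return cls(**flat)

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")


@dataclass
class PipelineResult:
    bundle: ResultBundle
    manifest: dict[str, str]
    distribution: DistributionSummary
    solo_calls: list[SoloCall] = field(default_factory=list)
    clusters: list[SequenceCluster] = field(default_factory=list)
    profiles: list[ContextProfile] = field(default_factory=list)


def read_corpus(input_dir: str | Path) -> list[AnnotatedGenome]:
    """Read every *.gff3 / *.faa / *.domains.tsv triplet in a directory."""
    input_dir = Path(input_dir)
    genomes = []
    for gff in sorted(input_dir.glob("*.gff3")):
        stem = gff.stem
        genomes.append(read_genome(gff, input_dir / f"{stem}.faa",
                                   input_dir / f"{stem}.domains.tsv"))
    return genomes


def _solos_table(calls: list[SoloCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        window_genes = ";".join(
            ",".join(sorted(n.pfams)) for n in c.neighborhood)
        rows.append({
            "genome_id": c.genome_id, "replicon_id": c.replicon_id,
            "protein_id": c.protein_id, "is_solo": c.is_solo,
            "blocking_luxI": c.blocking_luxI or "",
            "window_genes": window_genes, "luxr_length_ok": c.luxr_length_ok})
    return pd.DataFrame(rows, columns=SOLOS_COLUMNS)


def run_pipeline(genomes: list[AnnotatedGenome], out_dir: str | Path,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the configured stage prefix over a corpus and write all outputs."""
    cfg = config or PipelineConfig()
    cfg.validate()
    stages = set(cfg.stages)
    bundle = ResultBundle()
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "n_genomes": len(genomes)}

    calls: list[SoloCall] = []
    proteome: dict[str, str] = {}
    env_of_genome: dict[str, str | None] = {}
    if "detect" in stages:
        for g in genomes:
            calls.extend(detect_solos(g, window=cfg.window))
            proteome.update(g.proteome)
            env_of_genome[g.genome_id] = g.environment_label
        bundle.solos = _solos_table(calls)
        log.info("detect: %d LuxR calls, %d solos",
                 len(calls), sum(c.is_solo for c in calls))

    solo_calls = [c for c in calls if c.is_solo]
    counts: dict[str, int] = {}
    for c in solo_calls:
        counts[c.genome_id] = counts.get(c.genome_id, 0) + 1
    dist = summarize_distribution(counts, len(genomes))
    summary["distribution"] = dist.__dict__.copy()

    clusters: list[SequenceCluster] = []
    if "cluster" in stages and solo_calls:
        seqs = {c.protein_id: proteome[c.protein_id] for c in solo_calls}
        clusters = greedy_cluster(seqs, id_threshold=cfg.id_threshold,
                                  cov_threshold=cfg.cov_threshold)
        rows = []
        for cl in clusters:
            for pid, ident, (cm, cr) in zip(cl.member_ids, cl.member_identities,
                                            cl.member_coverages):
                rows.append({"cluster_id": cl.cluster_id,
                             "representative_id": cl.representative_id,
                             "member_id": pid, "identity_to_rep": round(ident, 6),
                             "cov_member": round(cm, 6), "cov_rep": round(cr, 6)})
        bundle.clusters = pd.DataFrame(rows, columns=CLUSTERS_COLUMNS)
        log.info("cluster: %d solos -> %d clusters", len(solo_calls), len(clusters))
    summary["n_clusters"] = len(clusters)

    call_by_pid = {c.protein_id: c for c in solo_calls}
    profiles: list[ContextProfile] = []
    if "profile" in stages and clusters:
        for cl in clusters:
            prof = build_context_profile(cl, call_by_pid,
                                         min_members=cfg.profile_min_members,
                                         freq_floor=cfg.profile_freq_floor)
            if prof is not None:
                profiles.append(prof)
        rows = [{"cluster_id": p.cluster_id, "pfam_acc": f,
                 "frequency": round(p.pfam_freqs[f], 6)}
                for p in profiles for f in p.retained_pfams]
        bundle.profiles = pd.DataFrame(rows, columns=PROFILES_COLUMNS)
        log.info("profile: %d clusters profiled (>%d members)",
                 len(profiles), cfg.profile_min_members - 1)
    summary["n_profiled_clusters"] = len(profiles)

    subgroup_of: dict[int, int] = {}
    if "subgroup" in stages:
        if len(profiles) >= 2:
            assignments = assign_subgroups(
                profiles, method=cfg.embed_method, seed=cfg.embed_seed,
                eps=cfg.dbscan_eps, min_samples=cfg.dbscan_min_samples)
            subgroup_of = {a.cluster_id: a.subgroup_id for a in assignments}
            bundle.subgroups = pd.DataFrame(
                [{"cluster_id": a.cluster_id,
                  "x": round(a.embedding[0], 6), "y": round(a.embedding[1], 6),
                  "z": round(a.embedding[2], 6), "subgroup_id": a.subgroup_id}
                 for a in assignments], columns=SUBGROUPS_COLUMNS)
        else:
            log.info("subgroup: skipped (%d profiled clusters < 2)", len(profiles))
    n_subgroups = len({s for s in subgroup_of.values() if s != -1})
    summary["n_subgroups"] = n_subgroups
    summary["n_noise_clusters"] = sum(1 for s in subgroup_of.values() if s == -1)

    class_of: dict[str, str] = {}
    if "classify" in stages and solo_calls:
        ref = _classify.load_reference_map(cfg.reference_map)
        rows = []
        for c in solo_calls:
            rep = _classify.score_conserved_residues(
                proteome[c.protein_id], ref, protein_id=c.protein_id)
            rep = _classify.classify_solo(rep, c, ref)
            class_of[c.protein_id] = rep.predicted_class_hint
            rows.append({
                "protein_id": rep.protein_id, "n_conserved": rep.n_conserved,
                "key_residues": rep.key_residue_string(),
                "pab_signature": rep.pab_signature,
                "motif_match": rep.motif_match,
                "neighborhood_class": rep.neighborhood_class,
                "predicted_class_hint": rep.predicted_class_hint})
        bundle.classes = pd.DataFrame(rows, columns=CLASSES_COLUMNS)
        log.info("classify: %d solos classified", len(rows))
    summary["class_counts"] = _value_counts(class_of)

    if "tree" in stages:
        reps = {cl.representative_id: proteome[cl.representative_id]
                for cl in clusters}
        if len(reps) >= 3:
            dm = distance_matrix(reps)
            tree = neighbor_joining(dm)
            cluster_of_rep = {cl.representative_id: cl.cluster_id
                              for cl in clusters}
            annotations = {}
            for rep_id in reps:
                call = call_by_pid[rep_id]
                annotations[rep_id] = {
                    "subgroup_id": subgroup_of.get(cluster_of_rep[rep_id]),
                    "class_hint": class_of.get(rep_id),
                    "environment_label": env_of_genome.get(call.genome_id)}
            bundle.tree_newick, bundle.tree_annotations = \
                write_annotated_newick(tree, annotations)
            summary["n_tree_leaves"] = len(reps)
        else:
            log.info("tree: skipped (%d representatives < 3)", len(reps))
            summary["n_tree_leaves"] = 0

    bundle.summary = summary
    manifest = write_outputs(bundle, out_dir)
    return PipelineResult(bundle=bundle, manifest=manifest, distribution=dist,
                          solo_calls=calls, clusters=clusters, profiles=profiles)


def _value_counts(mapping: dict[str, str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in mapping.values():
        out[v] = out.get(v, 0) + 1
    return dict(sorted(out.items()))
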