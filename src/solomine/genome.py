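"""Genome model and I/O.

A genome is read from three plain-text files: gene models (GFF3), the
proteome (FASTA) and precomputed protein-domain assignments (either the
HMMER3 per-domain tabular "domtblout" dialect or a simple 5-column TSV).
Neighborhood logic downstream works on gene *rank* (position in the
coordinate-sorted gene order of a replicon), so ranks are assigned here and
genes without protein products keep their slot in the order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import IntegrityError, ParseError

log = logging.getLogger(__name__)

PFAM_RE = re.compile(r"^PF\d{5}$")

SOLOS_COLUMNS = ["genome_id", "replicon_id", "protein_id", "is_solo",
                 "blocking_luxI", "window_genes", "luxr_length_ok"]
CLUSTERS_COLUMNS = ["cluster_id", "representative_id", "member_id",
                    "identity_to_rep", "cov_member", "cov_rep"]
PROFILES_COLUMNS = ["cluster_id", "pfam_acc", "frequency"]
SUBGROUPS_COLUMNS = ["cluster_id", "x", "y", "z", "subgroup_id"]
CLASSES_COLUMNS = ["protein_id", "n_conserved", "key_residues",
                   "pab_signature", "motif_match", "neighborhood_class",
                   "predicted_class_hint"]


@dataclass(frozen=True)
class Gene:
    """One gene model; coordinates are GFF3-style 1-based inclusive."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    rank: int
    protein_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise IntegrityError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise IntegrityError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class DomainHit:
    """One domain assignment on a protein (1-based inclusive residue coords)."""

    protein_id: str
    pfam_acc: str
    ali_start: int
    ali_end: int
    score: float

    def __post_init__(self) -> None:
        if not PFAM_RE.match(self.pfam_acc):
            raise IntegrityError(
                f"domain hit on {self.protein_id}: bad accession {self.pfam_acc!r}")
        if not 1 <= self.ali_start <= self.ali_end:
            raise IntegrityError(
                f"domain hit on {self.protein_id}: bad coordinates "
                f"{self.ali_start}..{self.ali_end}")


@dataclass
class AnnotatedGenome:
    """Replicons of ranked genes plus proteome and domain index."""

    genome_id: str
    replicons: dict[str, list[Gene]] = field(default_factory=dict)
    proteome: dict[str, str] = field(default_factory=dict)
    domains: dict[str, list[DomainHit]] = field(default_factory=dict)
    taxon_label: str = ""
    environment_label: str | None = None

    def pfams_of(self, protein_id: str | None) -> frozenset[str]:
        if protein_id is None:
            return frozenset()
        return frozenset(h.pfam_acc for h in self.domains.get(protein_id, ()))

    def genes(self) -> list[Gene]:
        return [g for rid in sorted(self.replicons) for g in self.replicons[rid]]

    def validate(self) -> None:
        for rid, genes in self.replicons.items():
            for i, g in enumerate(genes):
                if g.rank != i:
                    raise IntegrityError(
                        f"{self.genome_id}/{rid}: gene ranks not contiguous")
                if i and genes[i - 1].start > g.start:
                    raise IntegrityError(
                        f"{self.genome_id}/{rid}: genes not sorted by start")
                if g.protein_id is not None and g.protein_id not in self.proteome:
                    raise IntegrityError(
                        f"{self.genome_id}: protein {g.protein_id} of gene "
                        f"{g.gene_id} missing from proteome")
        for pid, hits in self.domains.items():
            if pid in self.proteome:
                plen = len(self.proteome[pid])
                for h in hits:
                    if h.ali_end > plen:
                        raise IntegrityError(
                            f"{self.genome_id}: domain {h.pfam_acc} on {pid} ends at "
                            f"{h.ali_end} beyond protein length {plen}")


def _read_metadata(gff_path: Path) -> dict[str, str]:
    meta = {}
    with open(gff_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = re.match(r"#!(\S+)\s+(.*)", line.strip())
            if m:
                meta[m.group(1)] = m.group(2)
    return meta


def _read_fasta(fasta_path: Path) -> dict[str, str]:
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq)
        if rec.id in proteome and proteome[rec.id] != seq:
            raise IntegrityError(
                f"{fasta_path}: duplicate protein {rec.id} with differing sequences")
        proteome[rec.id] = seq
    return proteome


def read_domain_table(path: Path) -> list[DomainHit]:
    """Parse domain assignments from a 5-column TSV or HMMER3 domtblout.

    TSV columns: protein_id, pfam_acc, ali_start, ali_end, score (header
    optional).  domtblout: whitespace-delimited with '#' comments; the
    target name, query accession, domain bitscore and "ali" coordinate
    columns are used and accession versions (PF03472.21) are stripped.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                f = line.split("\t")
                if f[0] == "protein_id":
                    continue
                if len(f) != 5:
                    raise ParseError(
                        f"{path}:{lineno}: expected 5 tab-separated fields, got {len(f)}")
                pid, acc, s, e, sc = f
            else:
                f = line.split()
                if len(f) < 19:
                    raise ParseError(
                        f"{path}:{lineno}: not a domtblout record ({len(f)} fields)")
                pid, acc, sc, s, e = f[0], f[4], f[13], f[17], f[18]
            try:
                hits.append(DomainHit(pid, acc.split(".")[0],
                                      int(s), int(e), float(sc)))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_genome(gff_path: str | Path, fasta_path: str | Path,
                domains_path: str | Path) -> AnnotatedGenome:
    """Assemble and validate an AnnotatedGenome from its three files.

    Domain hits on proteins absent from the proteome are kept but reported
    as warnings (they cannot block a whole genome).
    """
    gff_path, fasta_path, domains_path = map(Path, (gff_path, fasta_path, domains_path))
    for p in (gff_path, fasta_path, domains_path):
        if not p.exists():
            raise ParseError(f"input file not found: {p}")

    meta = _read_metadata(gff_path)
    genome_id = meta.get("genome-id", gff_path.stem)
    try:
        db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                                keep_order=True, merge_strategy="error")
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise ParseError(f"{gff_path}: malformed GFF3 ({exc})") from exc

    protein_of: dict[str, str] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        pid = cds.attributes.get("protein_id", [cds.id])[0]
        for parent in parents:
            protein_of[parent] = pid

    raw = list(db.features_of_type("gene"))
    if not raw:
        raise ParseError(f"{gff_path}: no gene features")

    replicons: dict[str, list[Gene]] = {}
    by_rep: dict[str, list] = {}
    for feat in raw:
        by_rep.setdefault(feat.seqid, []).append(feat)
    for rid in sorted(by_rep):
        feats = sorted(by_rep[rid], key=lambda f: (f.start, f.end, f.id))
        replicons[rid] = [
            Gene(gene_id=f.id, replicon_id=rid, start=f.start, end=f.end,
                 strand=f.strand, rank=i, protein_id=protein_of.get(f.id))
            for i, f in enumerate(feats)
        ]

    proteome = _read_fasta(fasta_path)
    domains: dict[str, list[DomainHit]] = {}
    for hit in read_domain_table(domains_path):
        if hit.protein_id not in proteome:
            log.warning("%s: domain hit on unknown protein %s (kept, unlinked)",
                        genome_id, hit.protein_id)
        domains.setdefault(hit.protein_id, []).append(hit)

    genome = AnnotatedGenome(
        genome_id=genome_id, replicons=replicons, proteome=proteome,
        domains=domains, taxon_label=meta.get("taxon", ""),
        environment_label=meta.get("environment"))
    genome.validate()
    return genome


@dataclass
class ResultBundle:
    """Everything a pipeline run produces, ready to serialize."""

    solos: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SOLOS_COLUMNS))
    clusters: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CLUSTERS_COLUMNS))
    profiles: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PROFILES_COLUMNS))
    subgroups: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SUBGROUPS_COLUMNS))
    classes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CLASSES_COLUMNS))
    tree_newick: str | None = None
    tree_annotations: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def write_outputs(results: ResultBundle, out_dir: str | Path) -> dict[str, str]:
    """Write the fixed output file set; returns {filename: sha256}.

    Identical results produce byte-identical files: tables are written with
    fixed headers and column order, floats at full repr, and summary.json
    with sorted keys and no timestamps.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "solos.tsv": (results.solos, SOLOS_COLUMNS),
        "clusters.tsv": (results.clusters, CLUSTERS_COLUMNS),
        "context_profiles.tsv": (results.profiles, PROFILES_COLUMNS),
        "subgroups.tsv": (results.subgroups, SUBGROUPS_COLUMNS),
        "ligand_classes.tsv": (results.classes, CLASSES_COLUMNS),
    }
    manifest: dict[str, str] = {}
    for name, (df, cols) in tables.items():
        df = df.reindex(columns=cols)
        df.to_csv(out / name, sep="\t", index=False)
        manifest[name] = _sha256(out / name)
    if results.tree_newick is not None:
        (out / "tree.nwk").write_text(results.tree_newick)
        manifest["tree.nwk"] = _sha256(out / "tree.nwk")
        if results.tree_annotations is not None:
            results.tree_annotations.to_csv(out / "tree_annotations.tsv",
                                            sep="\t", index=False)
            manifest["tree_annotations.tsv"] = _sha256(out / "tree_annotations.tsv")
    with open(out / "summary.json", "w") as fh:
        json.dump(results.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["summary.json"] = _sha256(out / "summary.json")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_genome_files(genome: AnnotatedGenome, out_dir: str | Path) -> list[Path]:
    """Write {genome_id}.gff3/.faa/.domains.tsv; round-trips via read_genome."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gid = genome.genome_id
    gff = out / f"{gid}.gff3"
    faa = out / f"{gid}.faa"
    dom = out / f"{gid}.domains.tsv"

    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#!genome-id {gid}\n")
        if genome.taxon_label:
            fh.write(f"#!taxon {genome.taxon_label}\n")
        if genome.environment_label:
            fh.write(f"#!environment {genome.environment_label}\n")
        for rid in sorted(genome.replicons):
            for g in genome.replicons[rid]:
                fh.write(f"{rid}\tsolomine\tgene\t{g.start}\t{g.end}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}\n")
                if g.protein_id is not None:
                    fh.write(f"{rid}\tsolomine\tCDS\t{g.start}\t{g.end}\t.\t"
                             f"{g.strand}\t0\tID={g.gene_id}.cds;"
                             f"Parent={g.gene_id};protein_id={g.protein_id}\n")

    with open(faa, "w") as fh:
        for pid in sorted(genome.proteome):
            fh.write(f">{pid}\n{genome.proteome[pid]}\n")

    with open(dom, "w") as fh:
        fh.write("protein_id\tpfam_acc\tali_start\tali_end\tscore\n")
        for pid in sorted(genome.domains):
            for h in genome.domains[pid]:
                fh.write(f"{pid}\t{h.pfam_acc}\t{h.ali_start}\t{h.ali_end}\t"
                         f"{h.score:g}\n")
    return [gff, faa, dom]
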