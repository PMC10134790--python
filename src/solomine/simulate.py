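"""Seeded synthetic corpora with planted ground truth.

The generator emulates the statistical structure of a proteobacterial
genome survey: most genomes carry zero or one LuxR solo and a minority
carry several (default mixture 0.462 / 0.394 / 0.144, the survey's
observed proportions with the rounding remainder absorbed by the
multi-solo term); a fraction of genomes carry a complete luxI/luxR pair
in tandem, convergent, divergent or complex arrangement; the rest of each
replicon is decoy genes with uninformative domains plus occasional
non-coding genes that still occupy neighborhood slots.

Planted solos descend from per-archetype ancestor proteins derived from
the packaged TraR-like anchor by heavy substitution (35% of unconstrained
positions), so different archetypes fall well below the 80% clustering
threshold while members (5% substitutions) stay well above it.  The nine
key residues — and any implanted diagnostic motif — are never mutated, so
a PAB archetype keeps its W57M/Y61W signature and a pyrone archetype its
TYDQCS motif.  Signature neighbor pfams are attached only to designated
window genes of their own solo; planted solos are kept >=9 gene ranks
apart so detection windows never overlap.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .align import AMINO_ACIDS
from .classify import CLASS_AHL, CLASS_PAB, CLASS_PYRONE, load_reference_map
from .errors import ConfigError
from .genome import AnnotatedGenome, DomainHit, Gene, write_genome_files

LUXR_PFAM = "PF03472"
LUXI_PFAM = "PF00765"
HTH_PFAM = "PF00196"

DECOY_PFAMS = ("PF00126", "PF00440", "PF00486", "PF00903", "PF01381",
               "PF02518", "PF03466", "PF04542", "PF08281", "PF00196")

_AA = np.array(list(AMINO_ACIDS))
_KEY_POSITIONS = (57, 61, 70, 71, 85, 113, 178, 182, 188)

TRUTH_COLUMNS = ["genome_id", "replicon_id", "gene_id", "protein_id", "role",
                 "planted_subgroup", "planted_class", "topology"]


@dataclass(frozen=True)
class Archetype:
    """One planted solo family: sequence signature + neighborhood signature."""

    name: str
    planted_class: str
    neighbor_pfams: dict[str, float] = field(default_factory=dict)
    pab_substitution: bool = False
    motif: str | None = None
    motif_position: int = 120  # 1-based start of the implanted motif


def default_archetypes() -> list[Archetype]:
    return [
        Archetype("ahl_generic", CLASS_AHL),
        Archetype("pab_pip", CLASS_PAB, {"PF00561": 1.0}, pab_substitution=True),
        Archetype("pyrone_pluR", CLASS_PYRONE, motif="TYDQCS"),
        Archetype("sdia_enteric", CLASS_AHL, {"PF00005": 1.0, "PF00072": 1.0}),
        Archetype("mfs1_like", CLASS_AHL, {"PF07690": 1.0}),
    ]


@dataclass
class GeneratorConfig:
    n_genomes: int = 10
    replicons_range: tuple[int, int] = (1, 2)
    genes_per_replicon: tuple[int, int] = (20, 40)
    solo_mixture: tuple[float, float, float] = (0.462, 0.394, 0.144)
    multi_solo_range: tuple[int, int] = (2, 3)
    pair_prob: float = 0.4
    topology_weights: dict[str, float] = field(default_factory=lambda: {
        "tandem": 0.5, "convergent": 0.3, "divergent": 0.1, "complex": 0.1})
    mutation_rate: float = 0.05
    ancestor_divergence: float = 0.35
    noncoding_prob: float = 0.05
    archetypes: list[Archetype] = field(default_factory=default_archetypes)
    taxa: tuple[str, ...] = ("Rhizobium", "Pseudomonas", "Burkholderia",
                             "Agrobacterium", "Escherichia")
    environments: tuple[str, ...] = ("plant", "terrestrial", "aquatic", "human")

    def validate(self) -> None:
        if abs(sum(self.solo_mixture) - 1.0) > 1e-9:
            raise ConfigError(
                f"solo mixture probabilities sum to {sum(self.solo_mixture)}, not 1")
        if not self.archetypes:
            raise ConfigError("at least one archetype is required")
        if self.genes_per_replicon[0] < 12:
            raise ConfigError("replicons need >=12 genes to host planted elements")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown generator config keys: {sorted(bad)}")
        if "archetypes" in raw:
            raw["archetypes"] = [Archetype(**a) for a in raw["archetypes"]]
        for key in ("replicons_range", "genes_per_replicon", "solo_mixture",
                    "multi_solo_range", "taxa", "environments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float,
            protected: frozenset[int]) -> str:
    """Substitute each unprotected position w.p. `rate` (positions 1-based)."""
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < rate
    for pos in protected:
        mask[pos - 1] = False
    for i in np.nonzero(mask)[0]:
        choices = _AA[_AA != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


def _protected_positions(arch: Archetype, anchor_len: int) -> frozenset[int]:
    prot = set(_KEY_POSITIONS)
    if arch.motif:
        prot.update(range(arch.motif_position,
                          arch.motif_position + len(arch.motif)))
    return frozenset(p for p in prot if 1 <= p <= anchor_len)


_FORBIDDEN_MOTIFS = ("TYDQCS", "TYDQYI")


def _make_ancestors(cfg: GeneratorConfig, rng: np.random.Generator
                    ) -> dict[str, tuple[str, frozenset[int]]]:
    anchor = load_reference_map().reference_sequence
    ancestors: dict[str, tuple[str, frozenset[int]]] = {}
    for arch in cfg.archetypes:
        protected = _protected_positions(arch, len(anchor))
        base = list(anchor)
        if arch.pab_substitution:
            base[57 - 1], base[61 - 1] = "M", "W"
        if arch.motif:
            for k, aa in enumerate(arch.motif):
                base[arch.motif_position - 1 + k] = aa
        base = "".join(base)
        for _attempt in range(100):
            seq = _mutate(rng, base, cfg.ancestor_divergence, protected)
            if _motifs_ok(seq, arch):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not build a motif-clean ancestor")
        ancestors[arch.name] = (seq, protected)
    return ancestors


def _motifs_ok(seq: str, arch: Archetype) -> bool:
    for m in _FORBIDDEN_MOTIFS:
        if m != arch.motif and m in seq:
            return False
    return True


def _member_sequence(rng: np.random.Generator, cfg: GeneratorConfig,
                     arch: Archetype, ancestors) -> str:
    ancestor, protected = ancestors[arch.name]
    for _attempt in range(100):
        seq = _mutate(rng, ancestor, cfg.mutation_rate, protected)
        if _motifs_ok(seq, arch):
            return seq
    raise RuntimeError("could not build a motif-clean member")  # pragma: no cover


def _place_elements(rng: np.random.Generator, n_genes: int, n_pair_slots: int,
                    n_solos: int) -> tuple[int | None, list[int]] | None:
    """Choose a pair start index and solo indices with clean separation.

    Solos keep >=5 ranks from the pair's luxI and >=9 ranks from each
    other so no detection window contains a foreign signature.  Returns
    None when the replicon cannot host everything.
    """
    pair_start: int | None = None
    occupied: list[int] = []
    if n_pair_slots:
        if n_genes <= n_pair_slots:
            return None
        pair_start = int(rng.integers(0, n_genes - n_pair_slots + 1))
        occupied = list(range(pair_start, pair_start + n_pair_slots))
    solos: list[int] = []
    candidates = [i for i in range(n_genes) if i not in occupied]
    for _ in range(n_solos):
        ok = [i for i in candidates
              if all(abs(i - s) >= 9 for s in solos)
              and (pair_start is None
                   or all(abs(i - p) >= 5 for p in occupied))]
        if not ok:
            return None
        choice = int(rng.choice(ok))
        solos.append(choice)
        candidates.remove(choice)
    return pair_start, solos


def simulate_corpus(cfg: GeneratorConfig, seed: int
                    ) -> tuple[list[AnnotatedGenome], pd.DataFrame]:
    """Generate annotated genomes in memory plus the planted-truth table."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    ancestors = _make_ancestors(cfg, rng)
    pair_ancestor = None
    for _ in range(100):
        cand = _mutate(rng, load_reference_map().reference_sequence,
                       cfg.ancestor_divergence, frozenset(_KEY_POSITIONS))
        if all(m not in cand for m in _FORBIDDEN_MOTIFS):
            pair_ancestor = cand
            break
    genomes: list[AnnotatedGenome] = []
    truth_rows: list[dict] = []
    topo_names = sorted(cfg.topology_weights)
    topo_p = np.array([cfg.topology_weights[t] for t in topo_names], dtype=float)
    topo_p /= topo_p.sum()

    for gi in range(cfg.n_genomes):
        gid = f"G{gi:04d}"
        n_solos = int(rng.choice([0, 1, -1], p=cfg.solo_mixture))
        if n_solos == -1:
            n_solos = int(rng.integers(cfg.multi_solo_range[0],
                                       cfg.multi_solo_range[1] + 1))
        has_pair = rng.random() < cfg.pair_prob
        topology = str(rng.choice(topo_names, p=topo_p)) if has_pair else None
        n_replicons = int(rng.integers(cfg.replicons_range[0],
                                       cfg.replicons_range[1] + 1))
        solo_archs = [cfg.archetypes[int(rng.integers(len(cfg.archetypes)))]
                      for _ in range(n_solos)]

        # distribute elements over replicons; the pair goes on replicon 0
        per_rep_solos: list[list[Archetype]] = [[] for _ in range(n_replicons)]
        for arch in solo_archs:
            per_rep_solos[int(rng.integers(n_replicons))].append(arch)

        genome = AnnotatedGenome(
            genome_id=gid,
            taxon_label=str(rng.choice(np.array(cfg.taxa))),
            environment_label=str(rng.choice(np.array(cfg.environments))))
        pcount = 0

        for ri in range(n_replicons):
            rid = f"{gid}_rep{ri}"
            pair_here = has_pair and ri == 0
            n_pair_slots = (3 if topology == "complex" else 2) if pair_here else 0
            n_genes = int(rng.integers(cfg.genes_per_replicon[0],
                                       cfg.genes_per_replicon[1] + 1))
            placement = None
            while placement is None:
                placement = _place_elements(rng, n_genes, n_pair_slots,
                                            len(per_rep_solos[ri]))
                if placement is None:
                    n_genes += 10
            pair_start, solo_idx = placement

            # plan per-slot roles
            roles: dict[int, tuple[str, Archetype | None]] = {}
            if pair_here:
                if topology == "complex":
                    roles[pair_start] = ("pair_luxI", None)
                    roles[pair_start + 1] = ("spacer", None)
                    roles[pair_start + 2] = ("pair_luxR", None)
                else:
                    roles[pair_start] = ("pair_luxI", None)
                    roles[pair_start + 1] = ("pair_luxR", None)
            for k, arch in zip(solo_idx, per_rep_solos[ri]):
                roles[k] = ("solo", arch)

            # signature-carrier slots per solo
            carriers: dict[int, list[str]] = {}
            for k, arch in zip(solo_idx, per_rep_solos[ri]):
                for pfam, prev in sorted(arch.neighbor_pfams.items()):
                    if rng.random() < prev:
                        options = [j for j in range(max(0, k - 4),
                                                    min(n_genes, k + 5))
                                   if j != k and j not in roles]
                        slot = int(rng.choice(options))
                        carriers.setdefault(slot, []).append(pfam)

            genes: list[Gene] = []
            pos = int(rng.integers(1, 500))
            for j in range(n_genes):
                role, arch = roles.get(j, ("decoy", None))
                gene_id = f"{gid}_r{ri}g{j:03d}"
                protein_id: str | None = None
                seq: str | None = None
                hits: list[DomainHit] = []
                strand = "+" if rng.random() < 0.5 else "-"

                if role == "solo":
                    seq = _member_sequence(rng, cfg, arch, ancestors)
                    strand = "+" if rng.random() < 0.5 else "-"
                elif role == "pair_luxR":
                    seq = _mutate(rng, pair_ancestor, cfg.mutation_rate,
                                  frozenset(_KEY_POSITIONS))
                elif role == "pair_luxI":
                    seq = _random_protein(rng, int(rng.integers(190, 230)))
                elif role == "spacer":
                    seq = _random_protein(rng, int(rng.integers(80, 140)))
                elif j in carriers or rng.random() >= cfg.noncoding_prob:
                    seq = _random_protein(rng, int(rng.integers(150, 300)))

                if seq is not None:
                    pcount += 1
                    protein_id = f"{gid}_p{pcount:04d}"
                    genome.proteome[protein_id] = seq
                    if role in ("solo", "pair_luxR"):
                        hits.append(DomainHit(protein_id, LUXR_PFAM, 10, 170,
                                              float(rng.integers(120, 220))))
                        hits.append(DomainHit(protein_id, HTH_PFAM, 180,
                                              min(len(seq), 235),
                                              float(rng.integers(40, 90))))
                    elif role == "pair_luxI":
                        hits.append(DomainHit(protein_id, LUXI_PFAM, 5,
                                              min(len(seq), 180),
                                              float(rng.integers(100, 200))))
                    else:
                        for pfam in carriers.get(j, []):
                            end = int(rng.integers(60, min(len(seq), 140)))
                            hits.append(DomainHit(protein_id, pfam, 5, end,
                                                  float(rng.integers(30, 120))))
                        if role == "decoy" and j not in carriers:
                            for pfam in rng.choice(np.array(DECOY_PFAMS),
                                                   size=int(rng.integers(0, 3)),
                                                   replace=False):
                                end = int(rng.integers(40, min(len(seq), 140)))
                                hits.append(DomainHit(protein_id, str(pfam), 5,
                                                      end,
                                                      float(rng.integers(20, 90))))
                    if hits:
                        genome.domains[protein_id] = hits

                length = 3 * len(seq) + 3 if seq else int(rng.integers(100, 500))
                start = pos + int(rng.integers(50, 201))
                end = start + length - 1
                pos = end

                # force pair geometry onto the planned strands
                if role == "pair_luxI":
                    strand = {"tandem": "+", "convergent": "+",
                              "divergent": "-", "complex": "+"}[topology]
                elif role == "pair_luxR":
                    strand = {"tandem": "+", "convergent": "-",
                              "divergent": "+", "complex": "+"}[topology]

                genes.append(Gene(gene_id=gene_id, replicon_id=rid, start=start,
                                  end=end, strand=strand, rank=j,
                                  protein_id=protein_id))
                if role in ("solo", "pair_luxR", "pair_luxI"):
                    truth_rows.append({
                        "genome_id": gid, "replicon_id": rid, "gene_id": gene_id,
                        "protein_id": protein_id, "role": role,
                        "planted_subgroup": arch.name if arch else "",
                        "planted_class": arch.planted_class if arch else "",
                        "topology": topology if role != "solo" else ""})
            genome.replicons[rid] = genes
        genome.validate()
        genomes.append(genome)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return genomes, truth


def generate_corpus(cfg: GeneratorConfig, seed: int, out_dir: str | Path
                    ) -> tuple[list[Path], Path]:
    """Write GFF3/FASTA/domain-TSV triplets plus truth.tsv; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, truth = simulate_corpus(cfg, seed)
    written: list[Path] = []
    for genome in genomes:
        written.extend(write_genome_files(genome, out))
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    return written, truth_path


def generate_profile_blobs(k_archetypes: int, clusters_per_archetype: int,
                           n_noise: int, separation: float = 1.0,
                           seed: int = 0):
    """Labeled synthetic context profiles for subgrouping validation.

    Each archetype owns a disjoint block of 6 pfam features raised to
    baseline + 0.8*separation; members jitter by +-0.05.  Noise profiles
    are uniform over [0, 1] on every feature.  Returns (profiles,
    true_labels) where labels are 0..k-1 and -1 for noise.
    """
    from .context import ContextProfile

    rng = np.random.default_rng(seed)
    n_features = max(12, 6 * k_archetypes)
    features = [f"PF{9000 + i:05d}" for i in range(n_features)]
    baseline = 0.1
    amplitude = baseline + 0.8 * separation
    profiles: list[ContextProfile] = []
    labels: dict[int, int] = {}
    cid = 0
    for a in range(k_archetypes):
        block = range(6 * a, 6 * a + 6)
        center = np.full(n_features, baseline)
        center[list(block)] = amplitude
        for _ in range(clusters_per_archetype):
            vec = np.clip(center + rng.uniform(-0.05, 0.05, n_features), 0, 1)
            profiles.append(_profile_from_vector(cid, features, vec))
            labels[cid] = a
            cid += 1
    for _ in range(n_noise):
        vec = rng.uniform(0, 1, n_features)
        profiles.append(_profile_from_vector(cid, features, vec))
        labels[cid] = -1
        cid += 1
    return profiles, labels


def _profile_from_vector(cid: int, features: list[str], vec: np.ndarray):
    from .context import FREQ_FLOOR, ContextProfile

    freqs = {f: float(v) for f, v in zip(features, vec)}
    retained = tuple(sorted(f for f, v in freqs.items() if v >= FREQ_FLOOR))
    return ContextProfile(cluster_id=cid, n_members=60, pfam_freqs=freqs,
                          retained_pfams=retained)
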