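"""LuxR-solo detection and luxI/luxR pair-topology classification.

A LuxR-family protein (autoinducer-binding domain, PF03472) is a *solo*
when none of the surrounding 8 genes — 4 up and 4 down in gene-rank order
on the same replicon — encodes a protein with the AHL-synthase domain
(PF00765).  The window is ordinal, truncates at replicon ends and never
wraps; neighbor strand is irrelevant.  Proteins carrying both domains are
flagged as fused synthase-regulators and excluded from solo status.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractViolationError
from .genome import AnnotatedGenome, Gene

LUXR_PFAM = "PF03472"
LUXI_PFAM = "PF00765"
LUXR_LENGTH_RANGE = (230, 270)
PAIR_LINKAGE_BP = 3000


@dataclass(frozen=True)
class NeighborGene:
    """A gene occupying one slot of a detection window."""

    gene_id: str
    protein_id: str | None
    pfams: frozenset[str]
    offset: int  # rank offset from the focal gene; 0 = self


@dataclass(frozen=True)
class SoloCall:
    protein_id: str
    genome_id: str
    replicon_id: str
    is_solo: bool
    neighborhood: tuple[NeighborGene, ...]
    blocking_luxI: str | None
    luxr_length_ok: bool
    fused: bool = False
    gene: Gene | None = None

    def neighborhood_pfams(self, exclude_self: bool = True,
                           exclude: frozenset[str] = frozenset({LUXR_PFAM})
                           ) -> frozenset[str]:
        """Union of pfams over the window, excluding the focal gene and
        uninformative accessions by default."""
        acc: set[str] = set()
        for n in self.neighborhood:
            if exclude_self and n.offset == 0:
                continue
            acc.update(n.pfams)
        return frozenset(acc - exclude)


def detect_solos(genome: AnnotatedGenome, window: int = 4,
                 luxr_pfam: str = LUXR_PFAM,
                 luxi_pfam: str = LUXI_PFAM) -> list[SoloCall]:
    """One SoloCall per protein carrying *luxr_pfam*, in (replicon, rank) order."""
    calls: list[SoloCall] = []
    for rid in sorted(genome.replicons):
        genes = genome.replicons[rid]
        pfams = [genome.pfams_of(g.protein_id) for g in genes]
        for idx, gene in enumerate(genes):
            if luxr_pfam not in pfams[idx]:
                continue
            fused = luxi_pfam in pfams[idx]
            lo = max(0, idx - window)
            hi = min(len(genes), idx + window + 1)
            neighborhood = tuple(
                NeighborGene(genes[k].gene_id, genes[k].protein_id,
                             pfams[k], k - idx)
                for k in range(lo, hi)
            )
            blocking = None
            for k in range(lo, hi):
                if k != idx and luxi_pfam in pfams[k]:
                    blocking = genes[k].protein_id
                    break
            if fused and blocking is None:
                blocking = gene.protein_id  # the fusion itself blocks solo status
            plen = len(genome.proteome.get(gene.protein_id or "", ""))
            calls.append(SoloCall(
                protein_id=gene.protein_id or gene.gene_id,
                genome_id=genome.genome_id,
                replicon_id=rid,
                is_solo=blocking is None,
                neighborhood=neighborhood,
                blocking_luxI=blocking,
                luxr_length_ok=LUXR_LENGTH_RANGE[0] <= plen <= LUXR_LENGTH_RANGE[1],
                fused=fused,
                gene=gene,
            ))
    return calls


@dataclass(frozen=True)
class PairTopology:
    luxr_id: str
    luxi_id: str
    arrangement: str  # tandem | convergent | divergent | complex
    intergenic_bp: int
    linked: bool


def classify_pair_topology(luxr: Gene, luxi: Gene) -> PairTopology:
    """Classify the geometric arrangement of a luxR/luxI gene pair.

    tandem: same strand, adjacent.  convergent: opposite strands pointing
    toward each other (tail-to-tail).  divergent: opposite strands pointing
    apart (head-to-head).  complex: one or more intervening genes,
    whatever the strands.  linked means the intergenic distance is under
    3,000 bp.  Head-to-head vs tail-to-tail naming in the literature is
    muddled; this classifier is strictly geometric (see docs).
    """
    if luxr.replicon_id != luxi.replicon_id:
        raise ContractViolationError(
            f"pair {luxr.gene_id}/{luxi.gene_id} spans replicons "
            f"{luxr.replicon_id} and {luxi.replicon_id}")
    first, second = (luxr, luxi) if luxr.start <= luxi.start else (luxi, luxr)
    intergenic = max(0, second.start - first.end - 1)
    n_between = abs(luxr.rank - luxi.rank) - 1
    if n_between >= 1:
        arrangement = "complex"
    elif luxr.strand == luxi.strand:
        arrangement = "tandem"
    elif first.strand == "+":  # -> <- : tails meet
        arrangement = "convergent"
    else:  # <- -> : pointing apart
        arrangement = "divergent"
    return PairTopology(
        luxr_id=luxr.gene_id, luxi_id=luxi.gene_id, arrangement=arrangement,
        intergenic_bp=intergenic, linked=intergenic < PAIR_LINKAGE_BP)
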