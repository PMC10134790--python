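"""Shared fixtures and in-memory genome builders."""

from __future__ import annotations

import numpy as np
import pytest

from solomine.detect import NeighborGene, SoloCall
from solomine.genome import AnnotatedGenome, DomainHit, Gene

LUXR = "PF03472"
LUXI = "PF00765"


def make_genome(pfam_rows: dict[str, list[frozenset[str] | set[str] | None]],
                genome_id: str = "T") -> AnnotatedGenome:
    """Build a genome from {replicon: [pfam set per gene, None = non-coding]}.

    Genes are laid out 1 kb apart on the + strand; every coding gene gets a
    141-aa dummy protein and one DomainHit per pfam.
    """
    genome = AnnotatedGenome(genome_id=genome_id)
    p = 0
    for rid, rows in pfam_rows.items():
        genes = []
        for i, pfams in enumerate(rows):
            start = 1 + i * 1000
            pid = None
            if pfams is not None:
                p += 1
                pid = f"{genome_id}_p{p}"
                genome.proteome[pid] = "M" + "K" * 140
                genome.domains[pid] = [
                    DomainHit(pid, acc, 5, 120, 50.0) for acc in sorted(pfams)]
            genes.append(Gene(gene_id=f"{genome_id}_{rid}_g{i}", replicon_id=rid,
                              start=start, end=start + 900, strand="+",
                              rank=i, protein_id=pid))
        genome.replicons[rid] = genes
    genome.validate()
    return genome


def make_solo_call(protein_id: str, neighbor_pfams: list[set[str]],
                   is_solo: bool = True) -> SoloCall:
    """A SoloCall whose window carries the given per-neighbor pfam sets."""
    neighborhood = [NeighborGene("self", protein_id, frozenset({LUXR}), 0)]
    for k, pf in enumerate(neighbor_pfams, start=1):
        neighborhood.append(
            NeighborGene(f"n{k}", f"{protein_id}_n{k}", frozenset(pf), k))
    return SoloCall(protein_id=protein_id, genome_id="T", replicon_id="r",
                    is_solo=is_solo, neighborhood=tuple(neighborhood),
                    blocking_luxI=None if is_solo else "blk",
                    luxr_length_ok=True)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def reference_map():
    from solomine.classify import load_reference_map

    return load_reference_map()
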