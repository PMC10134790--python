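"""Residue- and context-based ligand-class prediction for LuxR solos.

QS LuxR-family proteins share nine highly conserved residues in TraR
numbering: six lining the AHL-binding cavity (W57, Y61, D70, P71, W85,
G113) and three in the helix-turn-helix domain (E178, L182, G188).
Diagnostic deviations drive the class hints:

* PAB (plant-associated-bacteria) solos substitute W57->M and Y61->W and
  sit next to a proline-iminopeptidase (pip) gene;
* the pyrone/dialkylresorcinol receptors PluR and PauR carry TYDQCS /
  TYDQYI in place of the canonical WYDPWG six-residue set;
* SdiA-like enteric solos keep the AHL residues but live in a conserved
  transporter/regulator context.

The hint is exactly that — a hint: full residue conservation does not
imply AHL binding (ligand-independent solos retain it), so the output is
never a functional claim.

Queries are numbered by global alignment to a packaged synthetic TraR-like
anchor that carries the consensus residues at the literal positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .align import global_align, validate_protein
from .detect import SoloCall
from .errors import ContractViolationError

CLASS_AHL = "AHL_type"
CLASS_PAB = "PAB_type"
CLASS_PYRONE = "pyrone_DAR_type"
CLASS_NONE = "unclassified"


@dataclass(frozen=True)
class KeyPosition:
    position: int
    consensus: str
    domain: str  # ligand_binding | hth


@dataclass(frozen=True)
class ReferenceMap:
    reference_id: str
    reference_sequence: str
    key_positions: tuple[KeyPosition, ...]
    motifs: dict[str, str]
    pip_pfams: frozenset[str]
    sdia_context_pfams: frozenset[str]

    def __post_init__(self) -> None:
        positions = [k.position for k in self.key_positions]
        if positions != sorted(positions) or len(set(positions)) != len(positions):
            raise ValueError("key positions must be strictly increasing")
        for k in self.key_positions:
            if self.reference_sequence[k.position - 1] != k.consensus:
                raise ValueError(
                    f"reference residue at {k.position} is not {k.consensus}")


def load_reference_map(path: str | None = None) -> ReferenceMap:
    """Load the packaged reference map, or a user-supplied YAML."""
    if path is None:
        text = (resources.files("solomine.data") / "reference_map.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return ReferenceMap(
        reference_id=raw["reference_id"],
        reference_sequence=validate_protein(raw["reference_sequence"], "reference"),
        key_positions=tuple(KeyPosition(k["position"], k["consensus"], k["domain"])
                            for k in raw["key_positions"]),
        motifs=dict(raw["motifs"]),
        pip_pfams=frozenset(raw.get("pip_pfams", [])),
        sdia_context_pfams=frozenset(raw.get("sdia_context_pfams", [])),
    )


@dataclass(frozen=True)
class LigandClassReport:
    protein_id: str
    aligned_key_residues: dict[int, str | None] = field(default_factory=dict)
    n_conserved: int = 0
    pab_signature: bool = False
    motif_match: str = "none"  # canonical | pluR | pauR | none
    neighborhood_class: str = "other"  # pip_adjacent_PAB | sdiA_like | other
    predicted_class_hint: str = CLASS_NONE

    def key_residue_string(self) -> str:
        return "".join((self.aligned_key_residues.get(p) or "-")
                       for p in sorted(self.aligned_key_residues))


def anchor_align(query: str, ref: ReferenceMap) -> dict[int, str | None]:
    """Map each reference position to the aligned query residue (None = gap)."""
    query = validate_protein(query, "query")
    if len(query) < 50:
        raise ContractViolationError(
            f"query too short for anchoring ({len(query)} aa < 50)")
    aln = global_align(ref.reference_sequence, query)
    return aln.ref_to_query()


def score_conserved_residues(query: str, ref: ReferenceMap,
                             protein_id: str = "") -> LigandClassReport:
    """Count conserved key residues and scan for diagnostic motifs."""
    posmap = anchor_align(query, ref)
    key = {k.position: posmap.get(k.position) for k in ref.key_positions}
    n_conserved = sum(1 for k in ref.key_positions if key[k.position] == k.consensus)
    pab = key.get(57) == "M" and key.get(61) == "W"
    q = query.upper()
    motif = "none"
    for name in ("canonical", "pluR", "pauR"):  # canonical checked first
        if ref.motifs[name] in q:
            motif = name
            break
    return LigandClassReport(
        protein_id=protein_id, aligned_key_residues=key,
        n_conserved=n_conserved, pab_signature=pab, motif_match=motif)


def classify_solo(report: LigandClassReport, solo_call: SoloCall,
                  ref: ReferenceMap) -> LigandClassReport:
    """Complete a report with neighborhood class and class hint.

    Precedence: pyrone/DAR motif > PAB (signature or pip neighbor) > AHL
    (>=8 conserved residues without a divergent motif) > unclassified.
    Pure function of its inputs.
    """
    if not solo_call.is_solo:
        raise ContractViolationError(
            f"{solo_call.protein_id} is not a solo; classification applies to solos")
    neighborhood = solo_call.neighborhood_pfams()
    if neighborhood & ref.pip_pfams:
        ncls = "pip_adjacent_PAB"
    elif ref.sdia_context_pfams and ref.sdia_context_pfams <= neighborhood:
        ncls = "sdiA_like"
    else:
        ncls = "other"
    if report.motif_match in ("pluR", "pauR"):
        hint = CLASS_PYRONE
    elif report.pab_signature or ncls == "pip_adjacent_PAB":
        hint = CLASS_PAB
    elif report.n_conserved >= 8 and report.motif_match in ("canonical", "none"):
        hint = CLASS_AHL
    else:
        hint = CLASS_NONE
    return replace(report, neighborhood_class=ncls, predicted_class_hint=hint)
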