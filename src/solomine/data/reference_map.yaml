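# Reference map for TraR-anchored residue numbering.
#
# The reference sequence is a SYNTHETIC TraR-like anchor: 240 aa (within
# the 230-270 aa range typical of QS LuxR-family proteins) carrying the
# nine consensus residues at their literal TraR-numbering positions.  The
# residues between key positions are an arbitrary fixed filler, not TraR;
# a real TraR sequence can be substituted via configuration.
reference_id: TraR_anchor_synthetic
reference_sequence: >-
  FVKDVMSDEAQCTECKYNTHALPVVTTEGNPFYPDMMFEATVNVSSLAAKFIECVMWEATYELKGKFNKDPFRPQIECMRGAQKWLTKKRVDAQLRDKQNEMIFQSLIFGGLGTSVDSSRQHDIRLNQWGWIHIWWGINDWNEKDKGECKQMLSGKMGILDWKPRPVYSDSSQNPVWESNYLPDCRGGMWKQAVHCHHDMIISAPPGAAQNNWDAPPRSMHSCADVQGARNCKTPLQFPM
key_positions:
  - {position: 57, consensus: W, domain: ligand_binding}
  - {position: 61, consensus: Y, domain: ligand_binding}
  - {position: 70, consensus: D, domain: ligand_binding}
  - {position: 71, consensus: P, domain: ligand_binding}
  - {position: 85, consensus: W, domain: ligand_binding}
  - {position: 113, consensus: G, domain: ligand_binding}
  - {position: 178, consensus: E, domain: hth}
  - {position: 182, consensus: L, domain: hth}
  - {position: 188, consensus: G, domain: hth}
motifs:
  canonical: WYDPWG
  pluR: TYDQCS
  pauR: TYDQYI
# Neighborhood-rule accessions (configurable):
# proline iminopeptidase falls in the alpha/beta hydrolase fold family;
# the SdiA-like enteric context is an ABC transporter plus a
# response-regulator receiver domain.
pip_pfams: [PF00561]
sdia_context_pfams: [PF00005, PF00072]
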