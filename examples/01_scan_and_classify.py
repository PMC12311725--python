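"""Scan a peptide for the 8-cysteine framework and classify it.

The input is cocotide tC1, a 33-residue cysteine-rich peptide from
cacao beans. The scanner locates the eight framework cysteines, the
classifier separates ginsentide-like (one-residue CXC loop between
Cys V and VI) from chitin-binding hevein-like peptides, and the fixed
I-IV / II-VI / III-VII / V-VIII disulfide pattern is mapped onto the
matched positions.
"""

import crpforge as cf

rec = cf.SequenceRecord(id="tC1", seq=cf.TC1_SEQUENCE, kind="protein")
(match,) = cf.scan_crp_motif(rec)

print(f"sequence          {rec.seq}")
print(f"cysteine positions {match.cys_positions}")
print(f"loop lengths       {match.loop_lengths}")

cls = cf.classify_8c_hlp(match)
print(f"classification     {cls.label}  (evidence: {', '.join(cls.evidence)})")

for pair in cf.assign_connectivity(match):
    print(f"disulfide Cys {pair.roman_pair:8s} residues {pair.positions}")

comp = cf.compute_composition(rec.seq)
print(
    f"composition        {comp.length} residues, "
    f"Cys {comp.percents['C']}%, Gly {comp.percents['G']}%, "
    f"net charge {comp.net_formal_charge}"
)
# The one-residue loop between Cys V and VI marks this as ginsentide-like;
# 8 Cys at 24% of the sequence is the family's defining cysteine richness.
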