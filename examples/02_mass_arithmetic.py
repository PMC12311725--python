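"""Disulfide-aware mass arithmetic for MS verification.

Computes the monoisotopic mass of the disulfide-bonded peptide, the
[M+H]+ ion seen in MALDI, and the mass shift expected after reduction
and S-carbamidomethylation — the experiment used to count cysteines —
then inverts an observed shift back to a cysteine count.
"""

import crpforge as cf

seq = cf.TC1_SEQUENCE

native = cf.peptide_mass(seq, cf.MassOptions(n_disulfides=4))
print(f"native mass (4 disulfides)   {native:9.3f} Da")
print(f"[M+H]+                       {cf.mz(native, 1):9.3f} m/z")

shift = cf.reduction_alkylation_shift(n_cys=8, n_disulfides=4)
print(f"reduction+alkylation shift   {shift:9.3f} Da  (nominal {cf.nominal(shift)})")
print(f"alkylated mass               {native + shift:9.3f} Da")

ox = cf.modification_shift([cf.ModificationSpec("met_oxidation", 1)])
print(f"one Met -> Met(O) shift      {ox:9.4f} Da  (nominal {cf.nominal(ox)})")

n = cf.infer_cys_count(observed_shift=464.0, assume_max_ss=True, tol=2.0)
print(f"cysteines inferred from a 464 Da observed shift: {n}")
# A 464 Da shift pins the cysteine count at 8 (57.02 per alkylated Cys
# plus 2.02 per reduced disulfide), confirming the 8-Cys framework.
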