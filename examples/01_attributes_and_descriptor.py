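"""Decompose a pesticide SMILES into attributes and sum a descriptor.

The model never parses chemistry: a molecule is its SMILES line, and
the descriptor DCW is the sum of tuned correlation weights over the
line's attributes — single SMILES atoms (Sk), adjacent pairs (SSk) and
the three fragment-of-local-symmetry count codes.
"""

from mcqsar import MoleculeAttributes, compute_dcw, extract_fls, load_worked_example, tokenize

smiles = "O=C(O)c1nc(c(c(N)c1Cl)Cl)Cl"

ts = tokenize(smiles)
print(f"SMILES: {smiles}")
print(f"tokens ({len(ts)}): {' '.join(ts.tokens)}")

xyx, xyyx, xyzyx = extract_fls(smiles)
print(f"fragments of local symmetry: XYX={xyx} XYYX={xyyx} XYZYX={xyzyx}")

mol = MoleculeAttributes.from_smiles(smiles)
print(f"attribute multiset: {sum(mol.sk.values())} atoms, "
      f"{sum(mol.ssk.values())} pairs, codes {mol.fls}")

# the shipped worked example: 66 published weight rows for one pesticide
ref_mol, ref_table = load_worked_example()
dcw = compute_dcw(ref_mol, ref_table)
print(f"worked-example descriptor DCW(1,15) = {dcw:.2f}")
print("(each weight enters once per attribute occurrence; the model's "
      "prediction is an affine function of this sum)")
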