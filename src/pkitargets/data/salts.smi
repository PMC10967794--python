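# Counterion / solvent components removed during salt stripping.
# One SMILES per line; '#' starts a comment.  Matching is by canonical
# SMILES equality of the disconnected component.
Cl
Br
I
F
[Na+]
[K+]
[Li+]
[Ca+2]
[Mg+2]
[NH4+]
O
N
CC(=O)O
CC(=O)[O-]
OS(=O)(=O)O
[O-]S(=O)(=O)O
CS(=O)(=O)O
CS(=O)(=O)[O-]
OC(=O)C(=O)O
OC(=O)/C=C/C(=O)O
O=C(O)CC(O)(CC(=O)O)C(=O)O
O=[N+]([O-])O
Cc1ccc(S(=O)(=O)O)cc1
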