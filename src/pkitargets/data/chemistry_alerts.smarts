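# Reactive / assay-hostile structural alerts (demerit-style subset).
# Format: <rule_name><TAB><SMARTS>.  '#' starts a comment line.
# Stands in for the full proprietary medicinal-chemistry rule program;
# only hard substructure alerts, no demerit scoring or property cutoffs.
acyl_halide	C(=O)[Cl,Br,I]
sulfonyl_halide	S(=O)(=O)[Cl,Br,I]
isocyanate	N=C=O
isothiocyanate	N=C=S
diazonium	[N+]#N
azide	N=[N+]=[N-]
peroxide	[OX2][OX2]
aldehyde	[CX3H1](=O)[#6]
epoxide	C1OC1
aziridine	C1NC1
michael_nitroalkene	C=C[N+](=O)[O-]
alpha_halo_ketone	C(=O)C[Cl,Br,I]
anhydride	C(=O)OC(=O)
thiol	[#6][SX2H]
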