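# Pan-assay interference (PAINS) substructure subset.
# Format: <rule_name><TAB><SMARTS>.  '#' starts a comment line.
# A compact selection of frequently matched interference classes; the
# engine accepts any user-supplied catalog in the same format.
quinone_A	O=C1C=CC(=O)C=C1
quinone_B	O=C1C(=O)C=CC=C1
catechol_A	c1cc(O)c(O)cc1
azo_A	c1ccccc1N=Nc1ccccc1
rhodanine_A	S=C1SC(=O)C(=C)N1
ene_rhod_A	C=C1C(=O)NC(=S)S1
hzone_phenol_A	c1cc(O)ccc1C=NN
imine_one_A	C(=O)C=NN
mannich_A	c1cc(O)c(CN)cc1
anil_di_alk_A	c1cc(N(C)C)ccc1C=C
thio_urea_A	NC(=S)N
hydroxyphenyl_hydrazine	c1cc(O)ccc1NN
nitro_phenol	c1cc([N+](=O)[O-])ccc1O
beta_keto_anhydride	O=C1OC(=O)C=C1
styrene_nitro	C=Cc1ccc([N+](=O)[O-])cc1
acyl_hydrazone	C(=O)NN=C
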