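# Small reference corpus of common odorants (SMILES<space>name), MW < 200 Da.
CCO ethanol
CCCCCCO hexanol
c1ccsc1 thiophene
CC(=O)OCC ethyl_acetate
CCCC(=O)OCC ethyl_butyrate
CC(=O)OCC(C)C isobutyl_acetate
c1ccccc1O phenol
Cc1ccccc1 toluene
COc1ccccc1 anisole
CC(C)=CCCC(C)=CCO geraniol
CC1=CCC(CC1)C(C)C alpha-terpinene_like
CCCCCC(=O)C 2-heptanone
CCCCC=O pentanal
CC(C)CC=O isovaleraldehyde
CCSCC diethyl_sulfide
CCCS propanethiol
OCC(C)C isobutanol
CC(=O)C acetone
CCCCCC(=O)OC methyl_hexanoate
c1ccc2ccccc2c1 naphthalene
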