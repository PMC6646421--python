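"""Embedded library of RDKit-verified drug-like SMILES (synthetic fixture).

A combinatorially generated, canonicalized pool of small drug-like
structures used by the synthetic-data generator.  OUTLIER_SMILES are
structurally atypical entries (inorganic / polyhalogenated) emulating
the screening panel members that cluster apart from the rest.
"""

POOL_SMILES = [
    'BrC1CCCCC1',
    'BrC1CCCNC1',
    'BrC1CCCOC1',
    'Brc1ccc[nH]1',
    'Brc1cccc2[nH]ccc12',
    'Brc1cccc2ccccc12',
    'Brc1cccc2ncccc12',
    'Brc1ccccc1',
    'Brc1ccccc1-c1ccccc1',
    'Brc1cccnc1',
    'C1CCCCC1',
    'C1CCNCC1',
    'C1CCOCC1',
    'C=CC1CCCCC1',
    'C=CC1CCCNC1',
    'C=CC1CCCOC1',
    'C=CCCCCCCCCC(=O)O',
    'C=Cc1ccc[nH]1',
    'C=Cc1cccc2[nH]ccc12',
    'C=Cc1cccc2ccccc12',
    'C=Cc1cccc2ncccc12',
    'C=Cc1ccccc1',
    'C=Cc1ccccc1-c1ccccc1',
    'C=Cc1cccnc1',
    'CC(=O)NC1CCCCC1',
    'CC(=O)NC1CCCNC1',
    'CC(=O)NC1CCCOC1',
    'CC(=O)Nc1ccc(O)cc1',
    'CC(=O)Nc1ccc[nH]1',
    'CC(=O)Nc1cccc2[nH]ccc12',
    'CC(=O)Nc1cccc2ccccc12',
    'CC(=O)Nc1cccc2ncccc12',
    'CC(=O)Nc1ccccc1',
    'CC(=O)Nc1ccccc1-c1ccccc1',
    'CC(=O)Nc1cccnc1',
    'CC(=O)OC1CCCCC1',
    'CC(=O)OC1CCCNC1',
    'CC(=O)OC1CCCOC1',
    'CC(=O)Oc1ccc[nH]1',
    'CC(=O)Oc1cccc2[nH]ccc12',
    'CC(=O)Oc1cccc2ccccc12',
    'CC(=O)Oc1cccc2ncccc12',
    'CC(=O)Oc1ccccc1',
    'CC(=O)Oc1ccccc1-c1ccccc1',
    'CC(=O)Oc1ccccc1C(=O)O',
    'CC(=O)Oc1cccnc1',
    'CC(C)(C)C1CCCCC1',
    'CC(C)(C)C1CCCNC1',
    'CC(C)(C)C1CCCOC1',
    'CC(C)(C)c1ccc[nH]1',
    'CC(C)(C)c1cccc2[nH]ccc12',
    'CC(C)(C)c1cccc2ccccc12',
    'CC(C)(C)c1cccc2ncccc12',
    'CC(C)(C)c1ccccc1',
    'CC(C)(C)c1ccccc1-c1ccccc1',
    'CC(C)(C)c1cccnc1',
    'CC(C)Cc1ccc(C(C)C(=O)O)cc1',
    'CC(N)Cc1ccccc1',
    'CC12CCC3c4ccc(O)cc4CCC3C1CCC2O',
    'CC1CCCCC1',
    'CC1CCCNC1',
    'CC1CCCOC1',
    'CCC1CCCCC1',
    'CCC1CCCNC1',
    'CCC1CCCOC1',
    'CCCCC1CCCCC1',
    'CCCCC1CCCNC1',
    'CCCCC1CCCOC1',
    'CCCCc1ccc[nH]1',
    'CCCCc1cccc2[nH]ccc12',
    'CCCCc1cccc2ccccc12',
    'CCCCc1cccc2ncccc12',
    'CCCCc1ccccc1',
    'CCCCc1ccccc1-c1ccccc1',
    'CCCCc1cccnc1',
    'CCN(CC)CCNC(=O)c1ccc(N)cc1',
    'CCc1ccc[nH]1',
    'CCc1cccc2[nH]ccc12',
    'CCc1cccc2ccccc12',
    'CCc1cccc2ncccc12',
    'CCc1ccccc1',
    'CCc1ccccc1-c1ccccc1',
    'CCc1cccnc1',
    'CN(C)C1CCCCC1',
    'CN(C)C1CCCNC1',
    'CN(C)C1CCCOC1',
    'CN(C)c1ccc[nH]1',
    'CN(C)c1cccc2[nH]ccc12',
    'CN(C)c1cccc2ccccc12',
    'CN(C)c1cccc2ncccc12',
    'CN(C)c1ccccc1',
    'CN(C)c1ccccc1-c1ccccc1',
    'CN(C)c1cccnc1',
    'CN1CCC[C@H]1c1cccnc1',
    'COC(=O)C1CCCCC1',
    'COC(=O)C1CCCNC1',
    'COC(=O)C1CCCOC1',
    'COC(=O)c1ccc[nH]1',
    'COC(=O)c1cccc2[nH]ccc12',
    'COC(=O)c1cccc2ccccc12',
    'COC(=O)c1cccc2ncccc12',
    'COC(=O)c1ccccc1',
    'COC(=O)c1ccccc1-c1ccccc1',
    'COC(=O)c1cccnc1',
    'COC1CCCCC1',
    'COC1CCCNC1',
    'COC1CCCOC1',
    'COc1ccc[nH]1',
    'COc1cccc2[nH]ccc12',
    'COc1cccc2ccccc12',
    'COc1cccc2ncccc12',
    'COc1ccccc1',
    'COc1ccccc1-c1ccccc1',
    'COc1cccnc1',
    'CSCCC(N)C(=O)O',
    'Cc1ccc[nH]1',
    'Cc1cccc2[nH]ccc12',
    'Cc1cccc2ccccc12',
    'Cc1cccc2ncccc12',
    'Cc1ccccc1',
    'Cc1ccccc1-c1ccccc1',
    'Cc1cccnc1',
    'ClC1CCCCC1',
    'ClC1CCCNC1',
    'ClC1CCCOC1',
    'Clc1ccc[nH]1',
    'Clc1cccc2[nH]ccc12',
    'Clc1cccc2ccccc12',
    'Clc1cccc2ncccc12',
    'Clc1ccccc1',
    'Clc1ccccc1-c1ccccc1',
    'Clc1cccnc1',
    'Cn1c(=O)c2c(ncn2C)n(C)c1=O',
    'FC(F)(F)C1CCCCC1',
    'FC(F)(F)C1CCCNC1',
    'FC(F)(F)C1CCCOC1',
    'FC(F)(F)c1ccc[nH]1',
    'FC(F)(F)c1cccc2[nH]ccc12',
    'FC(F)(F)c1cccc2ccccc12',
    'FC(F)(F)c1cccc2ncccc12',
    'FC(F)(F)c1ccccc1',
    'FC(F)(F)c1ccccc1-c1ccccc1',
    'FC(F)(F)c1cccnc1',
    'FC1CCCCC1',
    'FC1CCCNC1',
    'FC1CCCOC1',
    'Fc1ccc[nH]1',
    'Fc1cccc2[nH]ccc12',
    'Fc1cccc2ccccc12',
    'Fc1cccc2ncccc12',
    'Fc1ccccc1',
    'Fc1ccccc1-c1ccccc1',
    'Fc1cccnc1',
    'N#CC1CCCCC1',
    'N#CC1CCCNC1',
    'N#CC1CCCOC1',
    'N#Cc1ccc[nH]1',
    'N#Cc1cccc2[nH]ccc12',
    'N#Cc1cccc2ccccc12',
    'N#Cc1cccc2ncccc12',
    'N#Cc1ccccc1',
    'N#Cc1ccccc1-c1ccccc1',
    'N#Cc1cccnc1',
    'NC(=O)C1CCCCC1',
    'NC(=O)C1CCCNC1',
    'NC(=O)C1CCCOC1',
    'NC(=O)c1ccc(N)cc1',
    'NC(=O)c1ccc[nH]1',
    'NC(=O)c1cccc2[nH]ccc12',
    'NC(=O)c1cccc2ccccc12',
    'NC(=O)c1cccc2ncccc12',
    'NC(=O)c1ccccc1',
    'NC(=O)c1ccccc1-c1ccccc1',
    'NC(=O)c1cccnc1',
    'NC(Cc1c[nH]c2ccccc12)C(=O)O',
    'NC1CCCCC1',
    'NC1CCCNC1',
    'NC1CCCOC1',
    'NCCC1CCCCC1',
    'NCCC1CCCNC1',
    'NCCC1CCCOC1',
    'NCCc1ccc(O)c(O)c1',
    'NCCc1ccc[nH]1',
    'NCCc1cccc2[nH]ccc12',
    'NCCc1cccc2ccccc12',
    'NCCc1cccc2ncccc12',
    'NCCc1ccccc1',
    'NCCc1ccccc1-c1ccccc1',
    'NCCc1cccnc1',
    'NS(=O)(=O)C1CCCCC1',
    'NS(=O)(=O)C1CCCNC1',
    'NS(=O)(=O)C1CCCOC1',
    'NS(=O)(=O)c1ccc[nH]1',
    'NS(=O)(=O)c1cccc2[nH]ccc12',
    'NS(=O)(=O)c1cccc2ccccc12',
    'NS(=O)(=O)c1cccc2ncccc12',
    'NS(=O)(=O)c1ccccc1',
    'NS(=O)(=O)c1ccccc1-c1ccccc1',
    'NS(=O)(=O)c1cccnc1',
    'Nc1ccc[nH]1',
    'Nc1cccc2[nH]ccc12',
    'Nc1cccc2ccccc12',
    'Nc1cccc2ncccc12',
    'Nc1ccccc1',
    'Nc1ccccc1-c1ccccc1',
    'Nc1cccnc1',
    'O=C(O)C1CCCCC1',
    'O=C(O)C1CCCNC1',
    'O=C(O)C1CCCOC1',
    'O=C(O)c1cc(O)c(O)c(O)c1',
    'O=C(O)c1ccc([N+](=O)[O-])cc1',
    'O=C(O)c1ccc[nH]1',
    'O=C(O)c1cccc2[nH]ccc12',
    'O=C(O)c1cccc2ccccc12',
    'O=C(O)c1cccc2ncccc12',
    'O=C(O)c1ccccc1',
    'O=C(O)c1ccccc1-c1ccccc1',
    'O=C(O)c1cccnc1',
    'O=S(=O)(O)c1ccccc1',
    'OC1CCCCC1',
    'OC1CCCNC1',
    'OC1CCCOC1',
    'OCC(O)C(O)C(O)C(O)CO',
    'OCC(O)COC1CCCCC1',
    'OCC(O)COC1CCCNC1',
    'OCC(O)COC1CCCOC1',
    'OCC(O)COc1ccc[nH]1',
    'OCC(O)COc1cccc2[nH]ccc12',
    'OCC(O)COc1cccc2ccccc12',
    'OCC(O)COc1cccc2ncccc12',
    'OCC(O)COc1ccccc1',
    'OCC(O)COc1ccccc1-c1ccccc1',
    'OCC(O)COc1cccnc1',
    'OCCC1CCCCC1',
    'OCCC1CCCNC1',
    'OCCC1CCCOC1',
    'OCCc1ccc[nH]1',
    'OCCc1cccc2[nH]ccc12',
    'OCCc1cccc2ccccc12',
    'OCCc1cccc2ncccc12',
    'OCCc1ccccc1',
    'OCCc1ccccc1-c1ccccc1',
    'OCCc1cccnc1',
    'Oc1ccc[nH]1',
    'Oc1cccc2[nH]ccc12',
    'Oc1cccc2ccccc12',
    'Oc1cccc2ncccc12',
    'Oc1ccccc1',
    'Oc1ccccc1-c1ccccc1',
    'Oc1cccnc1',
    'c1cc[nH]c1',
    'c1ccc(-c2ccccc2)cc1',
    'c1ccc2[nH]ccc2c1',
    'c1ccc2c(c1)oc1ccccc12',
    'c1ccc2ccccc2c1',
    'c1ccc2ncccc2c1',
    'c1ccc2nccnc2c1',
    'c1ccccc1',
    'c1ccncc1',
    'c1cocn1',
]

OUTLIER_SMILES = [
    'O1[AsH]O[AsH]O[AsH]1',
    'OC(O)C(Cl)(Cl)Cl',
    'ClCCCl',
]
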