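"""Curated drug-like SMILES used by the synthetic benchmark generator.

Every entry parses cleanly with rdkit and has 8-40 heavy atoms; the
list spans common pharmacophores (NSAIDs, kinase inhibitors, CNS
drugs, antibiotics, steroids, ...) so synthetic datasets cover a
realistic spread of molecular sizes and aromaticity.
"""

DRUG_SMILES: tuple[str, ...] = (
    'CC(=O)Oc1ccccc1C(=O)O',
    'CC(=O)Nc1ccc(O)cc1',
    'CC(C)Cc1ccc(C(C)C(=O)O)cc1',
    'COc1ccc2cc(C(C)C(=O)O)ccc2c1',
    'CC(C(=O)O)c1cccc(C(=O)c2ccccc2)c1',
    'O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl',
    'COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1',
    'Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1',
    'CCOc1ccc(NC(C)=O)cc1',
    'CC1=CC(=O)N(c2ccccc2)N1C',
    'Cn1c(=O)c2c(ncn2C)n(C)c1=O',
    'Cn1c(=O)c2[nH]cnc2n(C)c1=O',
    'Cn1cnc2c1c(=O)[nH]c(=O)n2C',
    'CN1CCCC1c1cccnc1',
    'CC(N)Cc1ccccc1',
    'COC(=O)C(c1ccccc1)C1CCCCN1',
    'CC(C)NCC(O)COc1ccc(CC(N)=O)cc1',
    'COCCc1ccc(OCC(O)CNC(C)C)cc1',
    'CC(C)NCC(O)COc1cccc2ccccc12',
    'CC(C)NCC(O)COc1cccc2[nH]ccc12',
    'COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]',
    'CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl',
    'COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC',
    'COc1ccc(C2Sc3ccccc3N(CCN(C)C)C(=O)C2OC(C)=O)cc1',
    'CC(CS)C(=O)N1CCCC1C(=O)O',
    'CCOC(=O)C(CCc1ccccc1)NC(C)C(=O)N1CCCC1C(=O)O',
    'NCCCCC(NC(CCc1ccccc1)C(=O)O)C(=O)N1CCCC1C(=O)O',
    'CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1',
    'CCCCC(=O)N(Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1)C(C(C)C)C(=O)O',
    'NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O',
    'NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl',
    'CC(=O)SC1CCC2(C)C(CCC3(C)C2CCC23CCC(=O)O2)C1',
    'CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O',
    'COC(=O)C(c1ccccc1Cl)N1CCc2sccc2C1',
    'CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21',
    'CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21',
    'Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1',
    'CC(C)OC(=O)C(C)(C)Oc1ccc(C(=O)c2ccc(Cl)cc2)cc1',
    'CN(C)C(=N)NC(N)=N',
    'Cc1ncc(C(=O)NCCc2ccc(S(=O)(=O)NC(=O)NC3CCCCC3)cc2)cn1',
    'CCCCNC(=O)NS(=O)(=O)c1ccc(C)cc1',
    'CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1',
    'CN(CCOc1ccc(CC2SC(=O)NC2=O)cc1)c1ccccn1',
    'CC12CC(=O)C3C(CCC4=CC(=O)C=CC43C)C1CCC2(O)C(=O)CO',
    'CC1CC2C3CCC4=CC(=O)C=CC4(C)C3(F)C(O)CC2(C)C1(O)C(=O)CO',
    'CC12CCC(=O)C=C1CCC1C2C(O)CC2(C)C1CCC2(O)C(=O)CO',
    'CC12CCC3c4ccc(O)cc4CCC3C1CCC2O',
    'CC(=O)C1CCC2C3CCC4=CC(=O)CCC4(C)C3CCC12C',
    'CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1',
    'CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21',
    'Fc1ccc(C2CCNCC2COc2ccc3c(c2)OCO3)cc1',
    'CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21',
    'COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1',
    'CC(NC(C)(C)C)C(=O)c1cccc(Cl)c1',
    'O=c1n(CCCN2CCN(c3cccc(Cl)c3)CC2)nc2ccccn12',
    'CN(C)CCC=C1c2ccccc2CCc2ccccc21',
    'CN(C)CCCN1c2ccccc2CCc2ccccc21',
    'O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1',
    'Cc1nc2n(c1CCN1CCC(c3noc4cc(F)ccc34)CC1)CCCC2=O',
    'CN1CCN(C2=Nc3ccccc3Nc3sc(C)cc32)CC1',
    'OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1',
    'CN1CCN(C2=Nc3cc(Cl)ccc3Nc3ccccc32)CC1',
    'CN1CCN2c3ccccc3Cc3cccnc3C2C1',
    'NC(=O)N1c2ccccc2C=Cc2ccccc21',
    'O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1',
    'Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1',
    'NCC1(CC(=O)O)CCCCC1',
    'CC(C)CC(CN)CC(=O)O',
    'CC1(C)OC2COC3(COS(N)(=O)=O)OC(C)(C)OC3C2O1',
    'CCC(C(N)=O)N1CCCC1=O',
    'CCCC(CCC)C(=O)O',
    'CCC1(c2ccccc2)C(=O)NCNC1=O',
    'CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O',
    'OC1N=C(c2ccccc2Cl)c2cc(Cl)ccc2NC1=O',
    'Cc1nnc2n1-c1ccc(Cl)cc1C(c1ccccc1)=NC2',
    'CN(C)C(=O)Cc1c(-c2ccc(C)cc2)nc2ccc(C)cn12',
    'CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5',
    'COc1ccc2c3c1OC1C(O)C=CC4C(C2)N(C)CCC314',
    'CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1',
    'COc1cccc(C2(O)CCCCC2CN(C)C)c1',
    'C=CCN1CCC23c4c5ccc(O)c4OC2C(=O)CCC3(O)C1C5',
    'CCC(=O)C(CC(C)N(C)C)(c1ccccc1)c1ccccc1',
    'CCOC(=O)C1(c2ccccc2)CCN(C)CC1',
    'CC1(C)SC2C(NC(=O)C(N)c3ccc(O)cc3)C(=O)N2C1C(=O)O',
    'CC1(C)SC2C(NC(=O)C(N)c3ccccc3)C(=O)N2C1C(=O)O',
    'CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O',
    'CC1=C(C(=O)O)N2C(=O)C(NC(=O)C(N)c3ccccc3)C2SC1',
    'O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O',
    'CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23',
    'CCn1cc(C(=O)O)c(=O)c2cc(F)c(N3CCNCC3)cc21',
    'COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC',
    'Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1',
    'Nc1ccc(S(=O)(=O)Nc2ncccn2)cc1',
    'Cc1ncc([N+](=O)[O-])n1CCO',
    'O=C(NC(CO)C(O)c1ccc([N+](=O)[O-])cc1)C(Cl)Cl',
    'NNC(=O)c1ccncc1',
    'NC(=O)c1cnccn1',
    'CCC(CO)NCCNC(CC)CO',
    'Nc1ccc(S(=O)(=O)c2ccc(N)cc2)cc1',
    'O=C1CN(N=Cc2ccc([N+](=O)[O-])o2)C(=O)N1',
    'OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F',
    'Nc1nc2c(ncn2COCCO)c(=O)[nH]1',
    'Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O',
    'Nc1ccn(C2CSC(CO)O2)c(=O)n1',
    'CCOC(=O)C1=CC(OC(CC)CC)C(NC(C)=O)C(N)C1',
    'NC(=O)c1ncn(C2OC(CO)C(O)C2O)n1',
    'Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1',
    'COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1',
    'C#Cc1cccc(Nc2ncnc3cc(OCCOC)c(OCCOC)cc23)c1',
    'CCN(CC)CCNC(=O)c1c(C)[nH]c(C=C2C(=O)Nc3ccc(F)cc32)c1C',
    'CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1',
    'Cc1nc(Nc2ncc(C(=O)Nc3c(C)cccc3Cl)s2)cc(N2CCN(CCO)CC2)n1',
    'COc1cc2ncnc(Nc3ccc(F)c(Br)c3)c2cc1OCC1CCN(C)CC1',
    'C=CC1CN2CCC1CC2C(O)c1ccnc2ccc(OC)cc12',
    'CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12',
    'CCN(CCO)CCCC(C)Nc1ccnc2cc(Cl)ccc12',
    'COc1cc(NC(C)CCCN)c2ncccc2c1',
    'CC1CCC2C(C)C(=O)OC3OC4(C)CCC1C23OO4',
    'CCc1nc(N)nc(N)c1-c1ccc(Cl)cc1',
    'CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1',
    'O=c1[nH]cc(F)c(=O)[nH]1',
    'Nc1ccn(C2OC(CO)C(O)C2(F)F)c(=O)n1',
    'S=c1[nH]cnc2nc[nH]c12',
    'CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1',
    'O=C(c1ccc(OCCN2CCCCC2)cc1)c1c(-c2ccc(O)cc2)sc2cc(O)ccc12',
    'CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCN(C)CC4)ccc3OCC)nc12',
    'CN1CC(=O)N2C(Cc3c([nH]c4ccccc34)C2c2ccc3c(c2)OCO3)C1=O',
    'CN(C)CCOC(c1ccccc1)c1ccccc1',
    'CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1',
    'OC(=O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1',
    'CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1',
    'Cc1nc[nH]c1CSCCNC(=NC)NC#N',
    'CNC(=CC#N)NCCSCc1ccc(CN(C)C)o1',
    'NC(N)=Nc1nc(CSCCC(N)=NS(N)(=O)=O)cs1',
    'O=c1[nH]cnc2[nH]ncc12',
    'COc1cc2c(c(OC)c1OC)-c1ccc(OC)c(=O)cc1C(NC(C)=O)CC2',
    'CCCN(CCC)S(=O)(=O)c1ccc(C(=O)O)cc1',
    'COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1',
    'Cc1nccn1CC1CCc2c(C1=O)c1ccccc1n2C',
    'O=c1[nH]c2ccccc2n1C1CCN(CCCN2CCCC2)CC1',
    'NCC(CC(=O)O)c1ccc(Cl)cc1',
    'NC(Cc1ccc(O)c(O)c1)C(=O)O',
    'COc1ccc2[nH]cc(CCNC(C)=O)c2c1',
    'NCCc1c[nH]c2ccc(O)cc12',
    'NCCc1ccc(O)c(O)c1',
    'CC(C)(C)NCC(O)c1ccc(O)c(CO)c1',
    'CC(C)(C)NCC(O)c1cc(O)cc(O)c1',
    'CNC(C)C(O)c1ccccc1',
    'NCCc1ccc(O)cc1',
    'NC(Cc1c[nH]c2ccccc12)C(=O)O',
    'NC(Cc1ccccc1)C(=O)O',
    'OCC(O)C1OC(=O)C(O)=C1O',
    'Nc1nc2ncc(CNc3ccc(C(=O)O)cc3)nc2c(=O)[nH]1',
)
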