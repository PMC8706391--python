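# Hsp90 inhibitor reference library: id, SMILES, binding energy (kcal/mol), family
M01	CCNC(=O)c1noc(-c2cc(Cl)c(O)cc2O)c1-c1ccc(OC)cc1	-7.9	resorcinol
M02	CCNC(=O)c1[nH]nc(-c2cc(Cl)c(O)cc2O)c1-c1ccc(OC)cc1	-8.0	resorcinol
M03	CCNC(=O)c1noc(c2cc(Cl)c(O)cc2O)c1c3ccc(C[NH+]4CCOCC4)cc3	-7.6	resorcinol
M04	O=c1[nH]nc(-c2cc(Br)c(O)cc2O)n1-c1ccccc1F	-8.1	resorcinol
M06	CCc1cc(-c2n[nH]c(C)c2-c2ccccc2F)c(O)cc1O	-8.7	resorcinol
M07	O=c1[nH]nc(-c2ccc(O)cc2O)n1-c1ccccc1F	-8.3	resorcinol
M09	COc1ccc(-c2c(-c3ccc(O)cc3O)n[nH]c2C)cc1	-8.3	resorcinol
M10	CN(Cc1ccco1)C(=O)c1cc(-c2n[nH]c(=O)n2-c2ccccc2F)c(O)cc1O	-9.6	resorcinol
M11	Cc1ccccc1-n1c(-c2cc(C(=O)N(C)Cc3cccs3)c(O)cc2O)n[nH]c1=O	-8.9	resorcinol
M12	CCCCN(C)C(=O)c1cc(-c2n[nH]c(=O)n2-c2ccccc2F)c(O)cc1O	-9.1	resorcinol
M13	Oc1cc(O)c(-c2ccnn2-c2ccccc2Cl)cc1CCc1ccccn1	-9.7	resorcinol
M14	CCCN(C)S(=O)(=O)c1cc(-c2n[nH]c(=O)n2-c2ccccc2F)c(O)cc1O	-8.6	resorcinol
M15	CC(C)N(C)S(=O)(=O)c1cc(-c2n[nH]c(=O)n2-c2ccccc2F)c(O)cc1O	-8.9	resorcinol
M25	CC(C)N(C)S(=O)(=O)c1cc(-c2n[nH]c(=O)n2-c2ccccc2Cl)c(O)cc1O	-8.1	resorcinol
M26	CCCN(C)C(=O)c1cc(-c2n[nH]c(=O)n2-c2ccccc2C)c(O)cc1O	-8.4	resorcinol
M27	Cc1ccccc1-n1c(-c2cc(C(=O)N(C)Cc3ccccc3)c(O)cc2O)n[nH]c1=O	-9.3	resorcinol
M28	CCCCCCN(C)C(=O)c1cc(-c2ccnn2-c2ccccc2C)c(O)cc1O	-9.0	resorcinol
M29	Cc1cccc(CN(C)C(=O)c2cc(-c3n[nH]c(=O)n3-c3ccccc3C)c(O)cc2O)c1	-10.5	resorcinol
M30	Cc1ccccc1-n1c(-c2cc(C(=O)N(C)CC3CCCO3)c(O)cc2O)n[nH]c1=O	-8.7	resorcinol
M31	CCCCN(C)C(=O)c1cc(-c2n[nH]c(=O)n2-c2ccccc2)c(O)cc1O	-9.3	resorcinol
M32	Cc1ccccc1-n1nccc1-c1cc(C(=O)N(C)Cc2ccco2)c(O)cc1O	-9.2	resorcinol
M33	Cc1ccccc1-n1c(-c2ccc(O)cc2O)n[nH]c1=O	-8.2	resorcinol
M34	O=c1[nH]nc(-c2ccc(O)cc2O)n1-c1ccccc1Cl	-8.1	resorcinol
M35	CCc1ccccc1-n1c(-c2ccc(O)cc2O)n[nH]c1=O	-8.2	resorcinol
M36	CCCN(C)C(=O)c1cc(-c2n[nH]c(=O)n2-c2ccccc2F)c(O)cc1O	-9.0	resorcinol
M61	CCNC(=O)c1noc(-c2cc(C(C)C)c(O)cc2O)c1-c1ccc(C[NH+]2CCOCC2)cc1	-8.2	resorcinol
M08	Cc1n[nH]c2cc(O)c(-c3ccnn3-c3ccccc3)cc12	-8.7	hydroxy-indazole
M37	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccc5c(c4)OCO5)cc23)c1	-11.3	hydroxy-indazole
M38	C[NH+]1CCC(c2ccc(N(C)C(=O)c3cc4c(CCC(C)(C)C)n[nH]c4cc3O)cc2)CC1	-9.2	hydroxy-indazole
M39	CCCCN(C)C(=O)c1n[nH]c2cc(O)c(C(=O)N(C)c3ccc(N4CCOCC4)cc3)cc12	-9.0	hydroxy-indazole
M40	CN(Cc1ccc(Cl)cc1)C(=O)c2cc3c(Cc4ccccc4)n[nH]c3cc2O	-10.6	hydroxy-indazole
M41	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)Cc4ccccc4)cc23)c1	-10.5	hydroxy-indazole
M42	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)Cc4ccc(Cl)cc4)cc23)c1	-10.4	hydroxy-indazole
M43	Oc1cc2[nH]nc(Cc3ccccc3)c2cc1-c1ccnn1-c1ccccc1	-9.7	hydroxy-indazole
M44	Cc1ccc(N(C)C(=O)c2cc3c(Cc4cccc(C)c4)n[nH]c3cc2O)cc1	-10.8	hydroxy-indazole
M45	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(N5CCOCC5)cc4)cc23)c1	-10.7	hydroxy-indazole
M46	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccccc4)cc23)c1	-10.5	hydroxy-indazole
M47	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(N5CCCCC5)cc4)cc23)c1	-10.9	hydroxy-indazole
M48	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(N(C)C)cc4)cc23)c1	-10.4	hydroxy-indazole
M49	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(N5CC[NH2+]CC5)cc4)cc23)c1	-10.7	hydroxy-indazole
M50	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(N5CCN(C)CC5)cc4)cc23)c1	-10.1	hydroxy-indazole
M62	CO[C@H]1CCN(C(=O)c2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(N5CCOCC5)cc4)cc23)C1	-8.4	hydroxy-indazole
M63	CO[C@H]1CCCN(C(=O)c2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(N5CCOCC5)cc4)cc23)C1	-9.5	hydroxy-indazole
M64	CN(C(=O)c1cc2c(C(=O)N3CCCC3)n[nH]c2cc1O)c1ccc(N2CCOCC2)cc1	-9.9	hydroxy-indazole
M65	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(N5CCOCC5=O)cc4)cc23)c1	-10.3	hydroxy-indazole
M66	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4ccc(F)cc4)cc23)c1	-10.7	hydroxy-indazole
M67	COc1cccc(N(C)C(=O)c2cc3c(Cc4cccc(C)c4)n[nH]c3cc2O)c1	-10.8	hydroxy-indazole
M68	Cc1cccc(Cc2n[nH]c3cc(O)c(C(=O)N(C)c4cccc(C)c4)cc23)c1	-11.0	hydroxy-indazole
M69	CN(C(=O)c1cc2c(cc1O)[nH]nc2C(=O)N1CCOCC1)c1ccc(N2CCOCC2)cc1	-10.3	hydroxy-indazole
M05	COc1ccc(-c2c(C#N)c(N)nc3sc(C(N)=O)c(N)c23)cc1OCCCC(=O)O	-8.4	others
M17	N#Cc1ccc(N2CCN(CCCc3c[nH]c4cc(O)c(C#N)cc34)CC2)cc1	-8.7	others
M18	Brc1cnc2[nH]cnc2c1C(=O)NC1c2ccccc2-c2c(-c3cnc4ccccc4c3)cccc21	4.7	others
M24	Nc1cc(C(=O)NC2c3ccccc3-c3c(-c4nc5ccncc5[nH]4)cccc32)ccn1	-4.5	others
M60	C#CCCCn1c(Cc2cc(OC)c(OC)c(OC)c2Cl)nc2c(N)nc(F)nc21	-8.0	others
M19	c1cnc2[nH]ccc2c1C(=O)N[C@@H]1c2ccccc2c2c1cccc2c1[nH]c2c(n1)cc(cc2)F	4.2	others
M20	O=C(NC1c2ccccc2-c2c(-c3nc4ccncc4[nH]3)cccc21)c1ccnc2[nH]ccc12	0.2	others
M58	Cc1cnc(Cn2ccc3c(Cl)nc(N)nc32)c(C)c1Cl	-9.0	others
M59	COc1c(C)cnc(Cn2cc(C#CCC(C)(C)O)c3c(Cl)nc(N)nc32)c1C	-6.9	others
M21	Cc1nn(-c2ccc(C(N)=O)c(N[C@H]3CC[C@H](O)CC3)c2)c2cccc(-c3cnc4ccccc4c3)c12	9.2	others
M22	Cc1cn(-c2ccc(C(N)=O)c(N[C@H]3CC[C@H](O)CC3)c2)c2c1C(=O)CC(C)(C)C2	-10.8	others
M23	Cc1cn(-c2ccc(C(N)=O)c(NC3CCC(=O)CC3)c2)c2c1C(=O)CC(C)(C)C2	-10.9	others
M51	Nc1nc(C(=O)N2Cc3ccc(O)cc3C2)c2ccccc2n1	-11.0	others
M52	Nc1nc(C(=O)N2Cc3ccccc3C2)c2cc(O)ccc2n1	-10.5	others
M53	C[NH+]1CCN(S(=O)(=O)c2ccccc2-c2ccc3nc(N)nc(C(=O)N4Cc5ccccc5C4)c3c2)CC1	-7.7	others
M54	CNCc1ccccc1-c1ccc2nc(N)nc(C(=O)N3Cc4ccccc4C3)c2c1	-11.3	others
M55	Nc1nc(C(=O)N2Cc3ccccc3C2)c2cc(-c3cc(F)c(F)cc3CCc3nnn[nH]3)ccc2n1	-10.8	others
M56	Nc1nc(C(=O)N2Cc3ccccc3C2)c2ccccc2n1	-11.0	others
M71	Cc1ccc2nc(N)nc(C(=O)N3Cc4ccccc4C3)c2c1	-11.0	others
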