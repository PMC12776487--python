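SYN:0001	limb morphogenesis (synthetic)	TP63	FGFR2	DLG1	MYH3	NIPBL	SYNGENE0270	SYNGENE0232	SYNGENE0315	SYNGENE0265	SYNGENE0349	SYNGENE0400	SYNGENE0398	SYNGENE0142	SYNGENE0160	SYNGENE0279	SYNGENE0250	SYNGENE0173	SYNGENE0377	SYNGENE0358	SYNGENE0058	SYNGENE0063	SYNGENE0031	SYNGENE0396	SYNGENE0211	SYNGENE0112	SYNGENE0040	SYNGENE0372	SYNGENE0050	SYNGENE0257	SYNGENE0399	SYNGENE0228	SYNGENE0144	SYNGENE0086	SYNGENE0124	SYNGENE0073	SYNGENE0044	SYNGENE0080	SYNGENE0272	SYNGENE0324	SYNGENE0208	SYNGENE0215	SYNGENE0213	SYNGENE0297	SYNGENE0258	SYNGENE0072
SYN:0002	craniofacial development (synthetic)	TP63	FGFR2	DLG1	NIPBL	ANKRD1	FOXD4L1	SYNGENE0134	SYNGENE0322	SYNGENE0342	SYNGENE0222	SYNGENE0367	SYNGENE0152	SYNGENE0318	SYNGENE0165	SYNGENE0173	SYNGENE0168	SYNGENE0073	SYNGENE0235	SYNGENE0385	SYNGENE0297	SYNGENE0233	SYNGENE0046	SYNGENE0129	SYNGENE0347	SYNGENE0033	SYNGENE0384	SYNGENE0191	SYNGENE0082	SYNGENE0155	SYNGENE0022	SYNGENE0359	SYNGENE0157	SYNGENE0192	SYNGENE0217	SYNGENE0253	SYNGENE0323	SYNGENE0163	SYNGENE0183	SYNGENE0265	SYNGENE0035	SYNGENE0050	SYNGENE0345	SYNGENE0246	SYNGENE0266	SYNGENE0332	SYNGENE0272	SYNGENE0377	SYNGENE0076	SYNGENE0122	SYNGENE0100	SYNGENE0193	SYNGENE0110	SYNGENE0018	SYNGENE0197	SYNGENE0154	SYNGENE0383
SYN:0003	meiotic recombination (synthetic)	PRDM9	SYNGENE0032	SYNGENE0111	SYNGENE0006	SYNGENE0044	SYNGENE0024	SYNGENE0342	SYNGENE0008	SYNGENE0128	SYNGENE0324	SYNGENE0082	SYNGENE0258	SYNGENE0109	SYNGENE0089	SYNGENE0133	SYNGENE0383	SYNGENE0366	SYNGENE0088	SYNGENE0399	SYNGENE0238	SYNGENE0040	SYNGENE0026	SYNGENE0334	SYNGENE0268	SYNGENE0076	SYNGENE0159	SYNGENE0246	SYNGENE0037	SYNGENE0345	SYNGENE0189	SYNGENE0047
SYN:0004	cardiac muscle development (synthetic)	MYH3	ANKRD1	SYNGENE0399	SYNGENE0119	SYNGENE0087	SYNGENE0349	SYNGENE0030	SYNGENE0378	SYNGENE0280	SYNGENE0120	SYNGENE0325	SYNGENE0238	SYNGENE0131	SYNGENE0272	SYNGENE0256	SYNGENE0064	SYNGENE0221	SYNGENE0209	SYNGENE0296	SYNGENE0356	SYNGENE0249	SYNGENE0025	SYNGENE0035	SYNGENE0271	SYNGENE0178	SYNGENE0027	SYNGENE0057	SYNGENE0152	SYNGENE0369	SYNGENE0288	SYNGENE0311	SYNGENE0126	SYNGENE0105	SYNGENE0117	SYNGENE0281	SYNGENE0050	SYNGENE0389
SYN:0005	epithelial adhesion (synthetic)	DLG1	FAM170A	SYNGENE0315	SYNGENE0329	SYNGENE0238	SYNGENE0308	SYNGENE0257	SYNGENE0276	SYNGENE0014	SYNGENE0160	SYNGENE0297	SYNGENE0262	SYNGENE0029	SYNGENE0025	SYNGENE0272	SYNGENE0249	SYNGENE0050	SYNGENE0065	SYNGENE0070	SYNGENE0004	SYNGENE0248	SYNGENE0321	SYNGENE0069	SYNGENE0101	SYNGENE0224	SYNGENE0134	SYNGENE0088	SYNGENE0254	SYNGENE0327	SYNGENE0002	SYNGENE0103	SYNGENE0164	SYNGENE0167	SYNGENE0351	SYNGENE0278	SYNGENE0115	SYNGENE0396	SYNGENE0151	SYNGENE0143	SYNGENE0367	SYNGENE0026	SYNGENE0052	SYNGENE0284	SYNGENE0365	SYNGENE0352	SYNGENE0381	SYNGENE0392
SYN:0006	housekeeping A (synthetic)	SYNGENE0245	SYNGENE0124	SYNGENE0286	SYNGENE0400	SYNGENE0274	SYNGENE0070	SYNGENE0205	SYNGENE0122	SYNGENE0071	SYNGENE0261	SYNGENE0328	SYNGENE0345	SYNGENE0293	SYNGENE0291	SYNGENE0241	SYNGENE0164	SYNGENE0290	SYNGENE0358	SYNGENE0051	SYNGENE0026	SYNGENE0171	SYNGENE0333	SYNGENE0042	SYNGENE0353	SYNGENE0235	SYNGENE0233	SYNGENE0393	SYNGENE0105	SYNGENE0127	SYNGENE0061	SYNGENE0252	SYNGENE0177	SYNGENE0237	SYNGENE0065	SYNGENE0374	SYNGENE0050	SYNGENE0058	SYNGENE0295	SYNGENE0249	SYNGENE0100	SYNGENE0001	SYNGENE0320	SYNGENE0399	SYNGENE0265	SYNGENE0203	SYNGENE0003	SYNGENE0324	SYNGENE0294	SYNGENE0218	SYNGENE0033	SYNGENE0309	SYNGENE0142	SYNGENE0208	SYNGENE0073	SYNGENE0078	SYNGENE0081	SYNGENE0178	SYNGENE0349	SYNGENE0067	SYNGENE0234
SYN:0007	housekeeping B (synthetic)	SYNGENE0258	SYNGENE0195	SYNGENE0262	SYNGENE0293	SYNGENE0255	SYNGENE0132	SYNGENE0169	SYNGENE0114	SYNGENE0159	SYNGENE0082	SYNGENE0013	SYNGENE0133	SYNGENE0122	SYNGENE0310	SYNGENE0185	SYNGENE0017	SYNGENE0158	SYNGENE0002	SYNGENE0328	SYNGENE0307	SYNGENE0109	SYNGENE0118	SYNGENE0224	SYNGENE0281	SYNGENE0318	SYNGENE0011	SYNGENE0387	SYNGENE0083	SYNGENE0056	SYNGENE0057	SYNGENE0152	SYNGENE0394	SYNGENE0097	SYNGENE0095	SYNGENE0280	SYNGENE0260	SYNGENE0205	SYNGENE0006	SYNGENE0267	SYNGENE0282	SYNGENE0209	SYNGENE0247	SYNGENE0168	SYNGENE0392	SYNGENE0196	SYNGENE0356	SYNGENE0078	SYNGENE0042	SYNGENE0055	SYNGENE0193	SYNGENE0022	SYNGENE0186	SYNGENE0329	SYNGENE0015	SYNGENE0324
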