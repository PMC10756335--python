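# drug_id	smiles — small-molecule library for synthetic datasets
aspirin	CC(=O)Oc1ccccc1C(=O)O
caffeine	Cn1cnc2c1c(=O)n(C)c(=O)n2C
ibuprofen	CC(C)Cc1ccc(cc1)C(C)C(=O)O
paracetamol	CC(=O)Nc1ccc(O)cc1
naproxen	COc1ccc2cc(ccc2c1)C(C)C(=O)O
nicotine	CN1CCCC1c1cccnc1
fluorouracil	O=c1[nH]cc(F)c(=O)[nH]1
methotrexate	CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)NC(CCC(=O)O)C(=O)O)cc1
sulfanilamide	NS(=O)(=O)c1ccc(N)cc1
procaine	CCN(CC)CCOC(=O)c1ccc(N)cc1
lidocaine	CCN(CC)CC(=O)Nc1c(C)cccc1C
warfarin	CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
diazepam	CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1
imatinib	Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1
gefitinib	COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1
erlotinib	COCCOc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC
sorafenib	CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1
sunitinib	CCN(CC)CCNC(=O)c1c(C)[nH]c(C=C2C(=O)Nc3ccc(F)cc32)c1C
atenolol	CC(C)NCC(O)COc1ccc(CC(N)=O)cc1
propranolol	CC(C)NCC(O)COc1cccc2ccccc12
metoprolol	COCCc1ccc(OCC(O)CNC(C)C)cc1
salbutamol	CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
chlorpromazine	CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21
imipramine	CN(C)CCCN1c2ccccc2CCc2ccccc21
fluoxetine	CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1
sertraline	CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21
citalopram	CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21
haloperidol	O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1
ketamine	CNC1(c2ccccc2Cl)CCCCC1=O
cimetidine	CC1=C(CSCCNC(=NC)NC#N)N=CN1
omeprazole	COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1
metformin	CN(C)C(=N)NC(=N)N
trimethoprim	COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC
sulfamethoxazole	Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1
ciprofloxacin	O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O
isoniazid	NNC(=O)c1ccncc1
pyrazinamide	NC(=O)c1cnccn1
ethambutol	CCC(CO)NCCNC(CC)CO
chloroquine	CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12
quinine	COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1
dapsone	Nc1ccc(S(=O)(=O)c2ccc(N)cc2)cc1
zidovudine	Cc1cn(C2CC(N=[N+]=[N-])C(CO)O2)c(=O)[nH]c1=O
acyclovir	Nc1nc2c(ncn2COCCO)c(=O)[nH]1
gemcitabine	Nc1ccn(C2OC(CO)C(O)C2(F)F)c(=O)n1
cytarabine	Nc1ccn(C2OC(CO)C(O)C2O)c(=O)n1
mercaptopurine	Sc1ncnc2[nH]cnc12
dasatinib	Cc1nc(Nc2ncc(s2)C(=O)Nc2c(C)cccc2Cl)cc(n1)N1CCN(CCO)CC1
tamoxifen	CCC(=C(c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1
letrozole	N#Cc1ccc(C(c2ccc(C#N)cc2)n2cncn2)cc1
anastrozole	CC(C)(C#N)c1cc(Cn2cncn2)cc(C(C)(C)C#N)c1
bicalutamide	CC(O)(CS(=O)(=O)c1ccc(F)cc1)C(=O)Nc1ccc(C#N)c(C(F)(F)F)c1
celecoxib	Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1
indomethacin	COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1
diclofenac	O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl
allopurinol	O=c1[nH]cnc2[nH]ncc12
theophylline	Cn1c(=O)c2[nH]cnc2n(C)c1=O
phenytoin	O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1
carbamazepine	NC(=O)N1c2ccccc2C=Cc2ccccc21
valproate	CCCC(CCC)C(=O)O
gabapentin	NCC1(CC(=O)O)CCCCC1
baclofen	NCC(CC(=O)O)c1ccc(Cl)cc1
dopamine	NCCc1ccc(O)c(O)c1
serotonin	NCCc1c[nH]c2ccc(O)cc12
melatonin	COc1ccc2[nH]cc(CCNC(C)=O)c2c1
benzocaine	CCOC(=O)c1ccc(N)cc1
vanillin	COc1cc(C=O)ccc1O
nifedipine	COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]
verapamil	COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC
amlodipine	CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl
captopril	CC(CS)C(=O)N1CCCC1C(=O)O
losartan	CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nn[nH]n2)cc1
hydrochlorothiazide	NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O
furosemide	NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl
vorinostat	O=C(NO)CCCCCCC(=O)Nc1ccccc1
thalidomide	O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1
lenalidomide	Nc1cccc2c1CN(C1CCC(=O)NC1=O)C2=O
methadone	CCC(=O)C(CC(C)N(C)C)(c1ccccc1)c1ccccc1
tramadol	COc1cccc(C2(O)CCCCC2CN(C)C)c1
ribavirin	NC(=O)c1ncn(C2OC(CO)C(O)C2O)n1
sildenafil	CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCN(C)CC4)ccc3OCC)nc12
vemurafenib	CCCS(=O)(=O)Nc1ccc(F)c(C(=O)c2c[nH]c3ncc(-c4ccc(Cl)cc4)cc23)c1F
estradiol	CC12CCC3c4ccc(O)cc4CCC3C1CCC2O
testosterone	CC12CCC3C(CCC4=CC(=O)CCC43C)C1CCC2O
progesterone	CC(=O)C1CCC2C1(C)CCC1C2CCC2=CC(=O)CCC12C
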