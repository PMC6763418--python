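# Reconstruction of 34 published simplified amino-acid alphabets.
# Groupings were re-assembled from the original source publications cited in
# the name column; where a study's exact published partition could not be
# recovered verbatim, a chemically plausible partition of the size the study
# favored stands in. Treat as a synthetic/reconstructed stand-in for the
# original curated table, not a verbatim transcription.
# id	name	category	groups
mahler66	Mahler & Cordes 1966	chemistry	GAVLIPFMW,STCYNQ,DE,KRH
lehninger	Lehninger 1975	chemistry	GAPVLIM,FYW,STCNQ,KRH,DE
dickerson69	Dickerson & Geis 1969	chemistry	AVLIMFWP,GSTYCNQ,DE,KRH
taylor86	Taylor 1986	chemistry	IVLM,FYWH,KR,DE,NQ,ST,AG,CP
weathers04	Weathers et al. 2004	chemistry	CFILMVW,AGHPSTY,DENQ,KR
dayhoff78	Dayhoff et al. 1978	sequence_alignment	AGPST,C,DENQ,FWY,HKR,ILMV
murphy00	Murphy et al. 2000	sequence_alignment	A,C,G,H,P,KR,ST,FWY,ILMV,DENQ
cannata02	Cannata et al. 2002	sequence_alignment	AST,C,G,P,DENQ,HKR,ILMV,FWY
fan03	Fan & Wang 2003	sequence_alignment	C,MFILV,WY,AG,TS,NH,QED,RK,P
li03	Li et al. 2003	sequence_alignment	C,FYW,ML,IV,G,P,ATS,NH,QED,RK
edgar04	Edgar 2004	sequence_alignment	A,C,G,P,ST,ILMV,FWY,DE,NQ,KR,H
kosiol04	Kosiol et al. 2004	sequence_alignment	A,C,G,P,ST,DENQ,FWY,HKR,ILMV
andersen04	Andersen & Brunak 2004	sequence_alignment	FILMVWY,ACGPST,DEHKNQR
lenckowski07	Lenckowski & Walczak 2007	sequence_alignment	ADKN,CFY,EQR,GST,HW,ILMV,P
susko07	Susko & Roger 2007	sequence_alignment	APST,DENG,QKR,MIVL,WC,FYH
albayrak06	Albayrak et al. 2006	sequence_alignment	CFILMVWY,AGPST,DENQ,HKR
chen07	Chen et al. 2007	sequence_alignment	AGPV,ILMF,CWY,STNQH,DEKR
risler88	Risler et al. 1988	structure_alignment	ILMVF,ASTG,DENQKRH,YW,C,P
riddle97	Riddle et al. 1997	structure_alignment	CFILMVWY,HKRNQ,DE,AST,GP
mirny99	Mirny & Shakhnovich 1999	structure_alignment	AVLIMCF,WY,STNQ,DEKRH,G,P
prlic00	Prlic et al. 2000	structure_alignment	ILMV,FWY,AGST,C,P,DENQ,HKR
melo06	Melo & Marti-Renom 2006	structure_alignment	AEQKR,CFILMVWY,DGNS,HPT
robson76	Robson & Suzuki 1976	protein_blocks	AEQHKR,DGNST,CFILMVWY,P
solis00	Solis & Rackovsky 2000	protein_blocks	AVC,DEG,FWY,HRK,ILM,NQS,PT
rogov01	Rogov & Nekrasov 2001	protein_blocks	AG,ST,DE,NQ,KR,H,ILMV,FWY,C,P
etchebest07	Etchebest et al. 2007	protein_blocks	G,P,C,ILVM,FYW,AST,NQDE,HKR
peterson09	Peterson et al. 2009	protein_blocks	A,C,G,P,H,ST,DE,NQ,KR,ILV,M,FWY
zuo09	Zuo & Li 2009	protein_blocks	AG,C,DE,FWY,H,KR,ILMV,NQ,P,ST
crippen91	Crippen 1991	contact_potentials	GSTAP,CFILMVWY,DENQH,KR
maiorov92	Maiorov & Crippen 1992	contact_potentials	CFILMVWY,AGPST,DEHKNQR
thomas96	Thomas & Dill 1996	contact_potentials	CFILMVWY,ADEGHKNPQRST
wang99	Wang & Wang 1999	contact_potentials	CMFILVWY,ATH,GP,DE,SNQRK
cieplak01	Cieplak et al. 2001	contact_potentials	ACFILMVWY,DEGHKNPQRST
liu02	Liu et al. 2002	contact_potentials	CFYW,MLIV,G,P,ATS,NH,QED,RK
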