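marker_id	name	kos
rubisco	RuBisCO	K01601,K01602
prk	Phosphoribulokinase	K00855
codh_acs	CO dehydrogenase (CoSH)/acetyl-CoA synthase complex	K00198
acs	Acetyl-CoA synthase	K14138
hbd	4-hydroxybutyryl-CoA dehydratase	K14534
mmo	Methane monooxygenase	K16157,K16158,K16159
icl	Isocitrate lyase	K01637
mas	Malate synthase	K01638
cox_large	Aerobic CODH large chain (coxL)	K03520
cox_medium	Aerobic CODH medium chain (coxM)	K03519
cox_small	Aerobic CODH small chain (coxS)	K03518
amo	Ammonia monooxygenase	K10944,K10945,K10946
nap	Periplasmic nitrate reductase	K02567,K02568
nar	Respiratory nitrate reductase	K00370,K00371,K00374
nir	Nitrite reductase	K00368,K15864
nor	Nitric oxide reductase	K04561,K02305
apr	Adenylylsulfate reductase	K00394,K00395
paps	Phosphoadenosine phosphosulfate reductase	K00390
dsr	Sulfite reductase	K11180,K11181
hyd_nife	Periplasmic [NiFe] hydrogenase	K06282,K06281
hyd_nifese	Periplasmic [NiFeSe] hydrogenase	K17993
hyd_fefe	NADP-reducing [FeFe] hydrogenase	K00532,K00533,K00534
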