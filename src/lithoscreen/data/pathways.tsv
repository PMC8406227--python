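pathway_id	name	kos
cbb	Calvin-Benson-Bassham cycle	K00855,K01601,K01602
rtca	Reductive TCA cycle	K15230,K15231,K00174,K00175
wl	Wood-Ljungdahl pathway	K05299,K15022,K01938,K01491,K00297,K15023,K14138,K00198,K00194,K00197,K00196,K00192
tca	TCA cycle	K01647,K01681,K00031,K00164,K01902,K01903,K00239,K01676,K00024
glycolysis	Glycolysis/gluconeogenesis	K00844,K01810,K00850,K01623,K00134,K00927,K01834,K01689,K00873
glyoxylate	Glyoxylate shunt	K01637,K01638
nitrate_reduction	Dissimilatory nitrate reduction (narGHI)	K00370,K00371,K00374
nitrate_reduction_periplasmic	Periplasmic nitrate reduction (napAB)	K02567,K02568
nitrite_reduction	Nitrite reduction to NO (nirK/nirS)	K00368,K15864
no_reduction	Nitric oxide reduction (norBC)	K04561,K02305
n2o_reduction	Nitrous oxide reduction (nosZ)	K00376
sulfate_reduction	Dissimilatory sulfate reduction (sat-apr-dsr)	K00958,K00394,K00395,K11180,K11181
co_oxidation	Aerobic CO oxidation (coxSML)	K03518,K03519,K03520
nife_hydrogenase	[NiFe] hydrogenase (hyaAB)	K06282,K06281
fefe_hydrogenase	NADP-reducing [FeFe] hydrogenase	K00532,K00533,K00534
cytochrome_c_oxidase	Cytochrome c oxidase (coxABCD)	K02274,K02275,K02276,K02277
cytochrome_cbb3_oxidase	Microaerobic cbb3-type oxidase	K00404,K00405,K00406,K00407
cytochrome_bd_oxidase	Cytochrome bd oxidase	K00425,K00426
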