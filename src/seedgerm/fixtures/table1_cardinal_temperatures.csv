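# schema_version=1.0
# Seed mass, cardinal temperatures (degC) and base temperature (degC) for 36 cover crop
# taxa (34 species + 2 varieties each of Vicia faba and Pisum sativum) from 6 botanical
# families. Means and sd_across_percentiles are taken over the four germination
# percentiles (20th, 30th, 40th, 50th of sown seeds). Base water potential is not part
# of this table. photosynthesis marks the two C4 Poaceae.
family,species,species_code,photosynthesis,seed_mass_mg,t0_mean,t0_sd,tmax_mean,tmax_sd,topt_mean,topt_sd,tb_mean,tb_sd
Asteraceae,Guizotia abyssinica,GA,C3,3.3,8.7,2.8,42.9,0.3,28.7,1.3,8.1,0.9
Asteraceae,Helianthus annuus,HA,C3,48.0,2.3,1.1,36.0,0.0,32.5,0.6,4.4,0.5
Brassicaceae,Brassica carinata,BC,C3,5.0,0.0,0.0,37.1,0.2,32.3,0.3,6.7,0.9
Brassicaceae,Brassica juncea,BJ,C3,3.0,0.3,0.6,37.8,1.4,33.7,0.6,6.8,0.5
Brassicaceae,Brassica napus,BN,C3,2.7,0.0,0.0,38.9,0.5,32.7,0.4,7.2,0.2
Brassicaceae,Brassica rapa,BR,C3,3.7,0.0,0.0,39.7,0.0,33.1,0.5,6.6,0.0
Brassicaceae,Camelina sativa,CS,C3,1.3,0.0,0.0,35.8,0.4,28.3,0.1,2.1,0.1
Brassicaceae,Eruca sativa,ES,C3,1.3,0.8,0.6,36.2,0.1,32.5,0.4,5.4,0.1
Brassicaceae,Raphanus sativus,RS,C3,13.0,1.2,0.9,39.5,0.0,37.2,0.2,7.3,0.6
Brassicaceae,Sinapis alba,SA,C3,8.0,0.0,0.0,40.4,0.3,29.6,0.7,1.2,0.1
Fabaceae,Lathyrus sativus,LS,C3,176.0,0.3,0.6,39.1,0.6,26.8,0.7,3.5,0.2
Fabaceae,Lens nigricans,LN,C3,21.5,0.3,0.5,37.4,1.4,31.8,2.2,0.8,1.4
Fabaceae,Lupinus angustifolius,LA,C3,179.4,1.3,0.8,35.4,4.2,25.7,3.7,0.8,0.1
Fabaceae,Medicago lupulina,ML,C3,1.5,2.1,0.5,30.3,4.8,26.2,4.1,0.6,0.4
Fabaceae,Melilotus officinalis,MO,C3,2.5,1.1,1.1,33.5,1.3,24.9,2.3,0.8,1.3
Fabaceae,Onobrychis viciifolia,OV,C3,23.0,1.8,1.1,31.7,0.2,24.2,1.2,0.0,0.0
Fabaceae,Pisum sativum ASSAS,PSA,C3,168.8,0.7,0.7,33.5,3.2,28.5,0.9,1.1,1.5
Fabaceae,Pisum sativum PFX,PSP,C3,214.5,0.0,0.0,32.0,0.6,29.3,1.3,7.3,0.8
Fabaceae,Trifolium alexandrinum,TA,C3,3.0,1.1,1.9,41.6,1.2,30.0,1.4,6.1,0.3
Fabaceae,Trifolium incarnatum,TI,C3,4.7,1.5,1.2,43.4,0.5,26.5,1.9,6.4,0.3
Fabaceae,Trigonella foenum-graecum,TFG,C3,16.0,0.0,0.0,43.0,0.0,30.1,0.3,4.2,1.0
Fabaceae,Vicia benghalensis,VB,C3,41.4,2.6,0.5,39.5,0.0,23.6,0.8,2.1,0.1
Fabaceae,Vicia faba LAURA,VFL,C3,442.8,0.2,0.4,33.9,2.7,23.8,2.6,0.0,0.0
Fabaceae,Vicia faba SSNS,VFS,C3,359.6,0.5,0.5,31.6,0.0,28.1,0.3,1.2,2.0
Fabaceae,Vicia sativa,VS,C3,53.8,0.6,1.0,30.0,1.7,22.0,0.8,4.1,0.0
Fabaceae,Vicia villosa,VV,C3,26.7,0.5,0.8,33.1,6.8,20.2,1.1,1.4,0.9
Hydrophylaceae,Phacelia tanacetifolia,PT,C3,1.8,0.3,0.6,27.7,1.0,21.3,1.0,3.6,0.1
Poaceae,Avena sativa,AV,C3,39.4,0.5,0.8,32.7,3.5,25.5,4.5,2.2,1.6
Poaceae,Avena strigosa,AS,C3,16.1,0.0,0.0,35.8,0.2,27.8,0.4,4.8,0.1
Poaceae,Lolium hybridum,LH,C3,3.4,0.9,0.7,36.0,0.0,29.0,0.3,1.1,0.3
Poaceae,Lolium multiflorum,LM,C3,2.7,0.4,0.3,34.6,1.3,30.1,0.1,1.9,0.3
Poaceae,Secale cereale,SC,C3,32.3,0.5,0.7,38.1,1.5,34.5,1.5,0.6,0.2
Poaceae,Secale multicaule,SM,C3,18.8,0.0,0.0,37.1,0.9,32.1,1.1,3.1,0.8
Poaceae,Setaria italica,SI,C4,2.2,11.3,0.3,39.5,0.0,36.1,1.5,10.6,0.1
Poaceae,Sorghum sudanense,SS,C4,13.8,5.3,3.0,40.6,1.5,35.6,3.0,9.4,0.6
Polygonaceae,Polygonum fagopyrum,PF,C3,25.0,3.8,0.4,39.4,0.2,32.3,0.4,7.8,0.9
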