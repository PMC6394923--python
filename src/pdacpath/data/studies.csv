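study_id,pathway,design,n,median_os,median_dfs
al_sukhun_2003,NAT,phase2,20,13.4,
cardenes_2011,NAT,phase2,28,10.3,
casadei_2015,NAT,phase2,18,28.3,
cetin_2013,NAT,phase2,11,,
chakraborty_2014,NAT,phase2,13,9.1,2.4
crane_2011,NAT,phase2,69,19.2,
epelbaum_2002,NAT,phase2,20,8,
esnaola_2014,NAT,phase2,37,11.8,10.4
evans_2008,NAT,phase2,86,22.7,15.4
fiore_2017,NAT,phase2,34,19.2,20
golcher_2015_a,NAT,phase2,121,,
golcher_2015_b,NAT,phase2,33,17.4,8.4
heinrich_2008,NAT,phase2,28,26.5,9.2
herman_2013,NAT,phase2,49,13.9,7.8
hong_2014,NAT,phase2,50,17.3,10.4
jang_2018,NAT,phase2,27,21,
jensen_2014,NAT,phase2,23,11.5,
joensuu_2004,NAT,phase2,33,25,18
kim_2013,NAT,phase2,68,18.2,
landry_2010,NAT,phase2,21,19.4,14.2
laurent_2017,NAT,phase2,22,17,8
le_scodan_2009,NAT,phase2,41,9.4,
lee_2012,NAT,phase2,43,16.6,10
leone_2013,NAT,phase2,39,16.7,10.2
lin_2012,NAT,phase2,42,10.3,
lind_2008,NAT,phase2,17,19,
magnin_2003,NAT,phase2,32,16,
magnino_2005,NAT,phase2,23,14,
marti_2008,NAT,phase2,26,13,7
mattiucci_2010,NAT,phase2,40,15.5,
massucco_2006,NAT,phase2,28,15.4,10
maximous_2009,NAT,phase2,25,12,
mornex_2006,NAT,phase2,41,9.4,
motoi_2013,NAT,phase2,35,19.7,
moutardier_2004,NAT,phase2,19,20,
oreilly_2014,NAT,phase2,38,27.2,
palmer_2007,NAT,phase2,50,13.6,
pipas_2012,NAT,phase2,37,17.3,
pister_2002,NAT,phase2,37,12,
sahora_2011,NAT,phase2,25,16,
satoi_2012,NAT,phase2,35,24.5,
sherman_2015,NAT,phase2,45,29,34
small_2008,NAT,phase2,29,11.8,9.9
talamonti_2006,NAT,phase2,20,,
tinchon_2013,NAT,phase2,12,,
turrini_2010,NAT,phase2,34,15.5,
van_buren_2013,NAT,phase2,59,16.8,6.6
varadhachary_2008,NAT,phase2,90,17.4,13.2
vento_2007,NAT,phase2,22,30.2,
wilkowski_2009,NAT,phase2,93,9.3,5.6
regine_2008_a,SF,RCT,230,17.1,
neoptolemos_2010_a,SF,RCT,551,23,14.1
van_laethem_2010_a,SF,RCT,45,24.3,11.8
schmidt_2012_a,SF,RCT,53,26.5,15.2
reni_2012_a,SF,RCT,51,26.2,11.7
yoshitomi_2008_a,SF,RCT,49,29.8,12
shimoda_2015_a,SF,RCT,29,21.5,14.6
uesaka_2016_a,SF,RCT,187,46.5,22.9
neoptolemos_2004_a,SF,RCT,145,15.9,10.7
ueno_2009_a,SF,RCT,58,22.3,11.4
oettle_2007_a,SF,RCT,179,22.8,13.4
kosuge_2006_a,SF,RCT,45,12.5,8.6
smeenk_2007_a,SF,RCT,110,21.6,18
morak_2010_a,SF,RCT,59,19,12
neoptolemos_2017_a,SF,RCT,366,25.5,
regine_2008_b,SF,RCT,221,20.5,
neoptolemos_2010_b,SF,RCT,537,23.6,14.3
van_laethem_2010_b,SF,RCT,45,24.4,10.9
schmidt_2012_b,SF,RCT,57,28.5,11.5
reni_2012_b,SF,RCT,49,31.6,15.2
yoshitomi_2008_b,SF,RCT,50,21.2,2.3
shimoda_2015_b,SF,RCT,28,18,10.5
uesaka_2016_b,SF,RCT,190,25.5,11.3
neoptolemos_2004_b,SF,RCT,147,20.1,15.3
ueno_2009_b,SF,RCT,60,18.4,5
oettle_2007_b,SF,RCT,175,20.2,6.7
kosuge_2006_b,SF,RCT,44,15.8,10.2
smeenk_2007_b,SF,RCT,108,19.2,14.4
morak_2010_b,SF,RCT,61,18,7
neoptolemos_2017_b,SF,RCT,364,28,
al_sukhun_2003_sf,SF,phase2,21,18.1,
casadei_2015_sf,SF,phase2,20,27.5,
golcher_2015_sf_a,SF,phase2,58,21,
golcher_2015_sf_b,SF,phase2,33,14.4,8.7
lind_2008_sf,SF,phase2,35,11,
massucco_2006_sf,SF,phase2,44,14,8
satoi_2012_sf,SF,phase2,41,18.5,
vento_2007_sf,SF,phase2,25,35.9,
jang_2018_sf,SF,phase2,23,12,
de_gus_2016,SF,cohort,6840,24.2,
mellon_2015,SF,cohort,241,22.1,
nurmi_2018,SF,cohort,150,26,13
shubert_2015,SF,cohort,216,13,
artinya_2017,SF,cohort,419,19,
ielpo_2017,SF,cohort,36,22.1,
roland_2015,SF,cohort,85,,
de_gus_2017,SF,cohort,11316,24.5,
mokdad_2016,SF,cohort,6015,21,
chen_2017,SF,cohort,98,17,
tzeng_2014,SF,cohort,52,25.3,
fujii_2015,SF,cohort,71,13.1,
fujii_2017,SF,cohort,416,23.5,
papalezova_2012,SF,cohort,92,13,
hirono_2017,SF,cohort,124,13.7,
murakami_2017,SF,cohort,25,11.6,
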