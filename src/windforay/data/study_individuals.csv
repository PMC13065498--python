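individual,gps_locations,sex,gps_model,birth_date,release_date,cohort,mrm_locations,lrm_locations
Artis 1,5485,M,Ecotone Crex,2017-04,2018-04-14,1,291,56
Artis 2,2810,F,Ecotone Crex,2017-04,2018-04-14,1,153,43
Artis 3,19278,F,Ornitela 3G_50G,2018-04,2019-06-24,2,666,64
Artis 4,9309,M,Ornitela 3G_50G,2018-04,2019-06-24,2,156,227
Artis 5,2384,M,Ecotone Crex,2018-04,2019-06-24,2,91,44
Barca,15784,F,Ecotone Skua,2015-04,2018-04-14,1,1227,358
Bulga,4618,F,Ecotone Crex,2015-04,2018-04-14,1,164,74
Calmedia,2816,F,Ecotone Crex,2018-04,2019-10-17,3,175,84
Caniga,8960,F,Ecotone Crex,2018-04,2019-10-17,3,290,214
Corte,4890,M,Ecotone Crex,2018-04,2019-10-17,3,209,135
Cristallo,13505,M,Ecotone Crex,2015-04,2018-04-14,1,487,426
Doglia,18090,F,Ornitela 3G_50G,2015-04,2019-10-17,3,468,274
Fenuggiu,10255,M,Ecotone Crex,2015-04,2018-04-14,1,486,94
Macomer,8012,F,Ecotone Saker,2018-04,2019-06-24,2,488,72
Meilogu,2484,M,Ecotone Crex,2018-04,2019-10-17,3,103,3
Pabelanasa,10526,F,Ecotone cDuck,2016-04,2018-12-12,4,614,251
Pituabile,6231,M,Ecotone Crex,2016-04,2018-12-12,4,222,73
Pozzomaggiore,6574,M,Ecotone Crex,2018-04,2019-06-24,2,680,108
Timidone,8451,M,Ecotone Crex,2018-04,2018-04-14,1,279,121
Tottubella,7740,F,Ecotone Crex,2018-04,2019-10-17,3,159,303
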