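fish_id,release_area,release_date,release_lat,release_lon,length_cm,sex,recovery_method_raw,recovery_method,drift_days,predated,stomach_days,max_depth_m,distance_recovered_km,liberty_days,liberty_censored,fate,max_distance_km,strategy,destination,note
A10903,EC,2014-11-04,50.621,-2.274,52,,Otter Trawl,fishery_trawl,,F,,76,41,300,F,Caught,138,intermediate,,
A10904,EC,2014-11-04,50.621,-2.274,44,,Gill Nets,fishery_net,,F,,94,234,382,F,Caught,374,long,NS,run-together digits 94234382 resolved as 94/234/382
A10898,EC,2014-11-04,50.621,-2.274,52,,Rod & line,fishery_rod,,F,,79,46,98,F,Caught,268,long,,run-together digits 794698 resolved as 79/46/98; strategy printed although liberty below 182 d
A10913,EC,2014-11-04,50.621,-2.274,51,,Rod & line,fishery_rod,,F,,49,16,46,F,Caught,73,,,run-together digits 491646 resolved as 49/16/46
A10892,EC,2014-11-05,50.688,-2.217,47,,Beached,beached,202,F,,42,188,24,F,Prem,116,,,run-together digits 4218824 resolved as 42/188/24
A10906,EC,2014-11-05,50.688,-2.217,53,,Beached,beached,35,F,,86,13,708,F,Prem,263,long,,run-together digits 8613708 resolved as 86/13/708
A10880,EC,2014-11-05,50.688,-2.217,55,,Beached,beached,135,T,10.36,83,206,292,F,Predated,109,intermediate,,
A10883,EC,2014-11-05,50.688,-2.217,47,,Beached,beached,701,F,,107,283,787,T,Unknown,419,long,CS,liberty printed as > 787
A10893,EC,2014-11-05,50.688,-2.217,62,,Long line,fishery_longline,,F,,,253,1097,F,Caught,,,,strategy column printed Tag lost
A10889,EC,2014-11-05,50.688,-2.217,48,,Rod & line,fishery_rod,,F,,105,78,225,F,Caught,106,intermediate,,
A10881,EC,2014-11-26,50.768,-2.354,47,M,Beached,beached,134,F,,103,155,678,F,Prem,122,intermediate,,
A10930,EC,2014-11-27,50.591,-2.318,44,,Fish Market,market,,F,,57,,34,F,Caught,45,,,
A10943,EC,2014-11-27,50.591,-2.318,45,,Beached,beached,9,F,,78,214,284,F,Prem,379,long,NS,
A10950,EC,2014-11-27,50.768,-2.354,47,F,Beached,beached,356,,,,159,1120,F,,,,,fate cell empty; strategy column printed Error
A10952,NS,2015-05-13,52.06,1.55,76,,Beached,beached,58,T,0.84,57,537,397,F,Predated,411,long,,
A10920,NS,2015-05-13,52.06,1.55,63,,Otter Trawl,fishery_trawl,,F,,59,12,364,F,Caught,45,short,,
A10932,NS,2015-05-13,52.06,1.55,58,,Gill Nets,fishery_net,,F,,53,4,373,F,Caught,45,short,,run-together digits 534373 resolved as 53/4/373
A10941,NS,2015-05-13,52.06,1.55,65,,Beached,beached,807,T,1.82,,819,617,F,Predated,,,,strategy column printed Error
A10978,NS,2017-05-18,52.4,1.75,52,,Beached,beached,12,F,,92,256,566,F,CaughtDiscarded,152,intermediate,EC,
A10939,NS,2015-05-24,52.396,1.753,57,,Fixed Nets,fishery_net,,F,,40,134,156,F,Caught,73,,,
A10918,NS,2015-05-24,52.396,1.753,62,F,Beached,beached,81,F,,95,84,748,F,Prem,450,long,EC,
A10947,NS,2015-05-24,52.396,1.753,52,,Beached,beached,2,F,,116,451,330,F,Prem,668,long,EC & CS,run-together digits 116451330 resolved as 116/451/330
A10931,NS,2015-05-24,52.396,1.753,58,,Long line,fishery_longline,,F,,57,2,368,F,Caught,41,short,,run-together digits 572368 resolved as 57/2/368
A10979,NS,2015-05-27,52.396,1.753,70,F,Long line,fishery_longline,,F,,56,31,218,F,Caught,21,short,,
A109742,NS,2015-05-27,52.396,1.753,56,,London draw,unknown,,F,,,,58,F,Caught,,,,id and recovery method garbled in source
A10978b,NS,2015-05-27,52.396,1.753,59,,Beached,beached,12,F,,92,143,192,F,,152,intermediate,EC,duplicate id A10978 retained with suffix; fate cell empty
A10961,NS,2015-05-27,52.396,1.753,49,M,Beached,beached,120,F,,,57,12,F,Death,,,,
A10964,NS,2015-05-27,52.396,1.753,56,M,Beached,beached,128,F,,50,571,800,F,Prem,52,intermediate,,run-together digits 50571800 resolved as 50/571/800
A10989,NS,2015-05-27,52.396,1.753,55,M,Beached,beached,72,F,,76,503,728,F,Prem,252,long,NS,
A10974,NS,2015-05-27,52.396,1.753,56,,Beached,beached,34,F,,,106,68,F,Prem,,,,
A10958,NS,2015-05-27,52.396,1.753,57,,Otter trawl,fishery_trawl,,F,,69,2,339,F,Caught,533,long,EC,run-together digits 692339 resolved as 69/2/339
A10988,NS,2015-05-27,52.396,1.753,60,,Rod & line,fishery_rod,,F,,95,421,430,F,Caught,387,long,EC & CS,run-together digits 95421430 resolved as 95/421/430 (population data-day total cross-check)
A10991,NS,2015-05-27,52.396,1.753,61,,Gill Nets,fishery_net,,F,,80,0,1435,F,Caught,214,intermediate,EC,printed intermediate although 214 km exceeds the 200 km threshold
A12694,NS,2017-05-18,52.082,1.56,57,,Unknown,unknown,,F,,,55,32,F,Caught,,,,
A10963,NS,2015-05-27,52.396,1.753,56,F,Beached,beached,5,,,,376,75,F,,,,,fate cell empty; strategy column printed Error; digits 37675 resolved as 376/75 (population data-day total cross-check)
A10955,NS,2017-05-19,52.07,1.513,53,,Landed,market,,F,,,,55,F,Caught,,,,
A13607,IS,2017-06-20,53.991,-3.025,70,,Beached,beached,15,F,,,374,36,F,Death,,,,strategy column printed Error
A13578,IS,2017-06-20,53.991,-3.025,64,,Beached,beached,128,T,1.59,,2,2,F,Predated,,,,digits 22 resolved as 2/2 (population minimum liberty cross-check)
A13573,IS,2017-06-20,54.058,-3.229,53,,Gill Nets,fishery_net,,F,,141,6,57,F,Caught,31,,,run-together digits 141657 resolved as 141/6/57 (Irish Sea maximum depth cross-check)
A13592,IS,2017-06-21,53.991,-3.025,55,,Beached,beached,75,T,0.68,,37,67,F,Predated,,,,
A13602,IS,2017-06-18,54.02,-3.02,61,,Rod & line,fishery_rod,,F,,14,184,15,F,Caught,419,long,CS,run-together digits 1418415 resolved as 14/184/15 (at-liberty-count cross-check); strategy printed although liberty below 182 d
A13601,IS,2018-07-16,54.237,-3.127,62,,Gill Nets,fishery_net,,F,,,19,104,F,Caught,,,,
A13623,IS,2017-06-21,54.031,-3.165,60,,Rod & line,fishery_rod,,F,,95,0,293,F,Caught,355,long,CS,run-together digits 950293 resolved as 95/0/293
A13629,IS,2017-06-18,53.9833,-3.0166,75,,Beached,beached,310,,,115,248,630,T,Prem,350,long,CS,liberty printed as > 630; predation cell printed as dash
A13624,IS,2017-06-18,53.9833,-3.0166,59,,Rod & line,fishery_rod,,F,,125,0,736,F,Caught,346,long,CS,run-together digits 1250736 resolved as 125/0/736
A13618,IS,2017-06-21,54.0333,-3.1666,51,,Beached,beached,10,F,,,8,18,F,Death,,,,
A13589,IS,2017-06-19,53.991,-3.025,67,,Beached,beached,169,T,,,263,93,F,,,,,predation flag without stomach days or fate label; excluded from fate counts; results text places the beaching 374-391 km from release which conflicts with the printed digits
A15274,IS,2018-07-18,54.1166,-3.0166,63,,Beached,beached,57,F,,103,62,275,F,Prem,283,long,CS,
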