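name,search_seed,params_id,beta_Hb,beta_Kr,beta_Pdm,beta_Cas,beta0_Pdm,beta0_Cas,alpha_Hb,alpha_Kr,alpha_Pdm,alpha_Cas,T_HbKr,T_KrPdm,T_HbPdm,T_PdmCas,T_KrCas,T_HbCas,T_CasPdm,robustness_score,decay_significance,relay_significance,t_wt_Hb,t_wt_Kr,t_wt_Pdm,t_wt_Cas
consistent,202,s202-d735,0.0125512412617225,1.5138586213852443,0.030800027876576,2.588629717093548,0.4500250483174131,0.7343542720413797,0.365813934534665,0.0226930087311897,0.0677074259475746,0.007433864723715,0.0014302149815845,4.789900707391252,0.0005211692951049,0.21969851352027,2.510195988523019,0.0004398961697899,7.069304973825271,0.0,93.94328180937114,15.0248105443484,0.1632023485132729,2.3955004589902247,56.93110522444535,182.18956171248163
robust,202,s202-d2549,0.5176690923267664,1.6799977256505296,0.5062838996271908,0.1113334204213234,0.6114227141857327,0.0586776020935815,0.3848546793058118,0.0233964232877363,0.0763984581043651,0.0108889095282881,0.0566566410210041,0.7884639470493471,0.0173362896919517,0.5517457595798894,0.7556144773541977,0.0137550284538305,0.8914423435619594,100.0,99.37086635924362,10.711362101748374,0.1565187912446799,2.322581616698763,56.64992531708225,228.31446498170712
decay_dominant,202,s125202-d4272,0.4614205943114889,2.478799500285335,0.0236296411325175,0.0426576285416227,0.0892150809075165,0.0071930696892365,0.3435875062187861,0.0253370409073853,0.0552982337608038,0.006722297209825,0.1226455314769862,2.612220081704073,0.0216661204049605,0.0687682838829536,1.0996089613122106,0.0193686528620546,0.6808021533310461,87.5,91.89129386827636,15.408161507292768,0.1719521456509976,2.3437967241360864,57.67246339107826,218.95472383452665
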