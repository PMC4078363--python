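algorithm_id,subset,tp,tn,fn,fp,post_test_prev,sensitivity,specificity,ppv,npv
h1_ever,adults,15,7429,54,2,0.2,22 (12-32),100 (100-100),88 (73-100),99 (99-100)
h1_or_er1,adults,16,7427,53,4,0.3,23 (13-33),100 (100-100),80 (63-98),99 (99-100)
p1_ever,adults,62,7188,7,243,4.1,90 (83-97),97 (96-97),20 (16-25),100 (100-100)
p1_spec_ever,adults,56,7377,13,54,1.5,81 (72-90),99 (99-100),51 (42-60),100 (100-100)
p2_any_1y,adults,58,7363,11,68,1.7,84 (75-93),99 (99-99),46 (37-55),100 (100-100)
p2_any_2y,adults,58,7359,11,72,1.7,84 (75-93),99 (99-99),45 (36-53),100 (100-100)
p2_any_3y,adults,58,7352,11,79,1.8,84 (75-93),99 (99-99),42 (34-51),100 (100-100)
p3_any_1y,adults,55,7398,14,33,1.2,80 (70-89),100 (99-100),63 (52-73),100 (100-100)
p3_any_2y,adults,55,7395,14,36,1.2,80 (70-89),100 (99-100),60 (50-71),100 (100-100)
p3_any_3y,adults,55,7393,14,38,1.2,80 (70-89),100 (99-100),59 (49-69),100 (100-100)
p2_spec_1y,adults,54,7404,15,27,1.1,78 (69-88),100 (100-100),67 (56-77),100 (100-100)
p2_spec_2y,adults,54,7404,15,27,1.1,78 (69-88),100 (100-100),67 (56-77),100 (100-100)
p2_spec_3y,adults,54,7401,15,30,1.1,78 (69-88),100 (100-100),64 (54-75),100 (100-100)
p3_spec_1y,adults,53,7419,16,12,0.9,77 (67-87),100 (100-100),82 (72-91),100 (100-100)
p3_spec_2y,adults,53,7418,16,13,0.9,77 (67-87),100 (100-100),80 (71-90),100 (100-100)
p3_spec_3y,adults,53,7418,16,13,0.9,77 (67-87),100 (100-100),80 (71-90),100 (100-100)
h1_or_p2_spec_1y,adults,55,7403,14,28,1.1,80 (70-89),100 (100-100),66 (56-76),100 (100-100)
h1_or_p2_spec_2y,adults,55,7403,14,28,1.1,80 (70-89),100 (100-100),66 (56-76),100 (100-100)
h1_or_p2_spec_3y,adults,55,7400,14,31,1.1,80 (70-89),100 (99-100),64 (54-74),100 (100-100)
h1_or_p3_spec_1y,adults,54,7417,15,14,0.9,78 (69-88),100 (100-100),79 (70-89),100 (100-100)
h1_or_p3_spec_2y,adults,54,7416,15,15,0.9,78 (69-88),100 (100-100),78 (69-88),100 (100-100)
h1_or_p3_spec_3y,adults,54,7416,15,15,0.9,78 (69-88),100 (100-100),78 (69-88),100 (100-100)
h1_or_p2_gap8w_2y,adults,57,7378,12,53,1.5,83 (74-92),99 (99-100),52 (43-61),100 (100-100)
h1_or_p2_gap8w_2y_exAB,adults,41,7401,28,30,0.9,59 (48-71),100 (100-100),58 (46-69),100 (100-100)
h1_or_p2_gap8w_3y_exAB,adults,41,7396,28,35,1.0,59 (48-71),100 (99-100),54 (43-65),100 (100-100)
h1_or_p2_gap8w_4y_exAB,adults,43,7394,26,37,1.1,62 (51-74),100 (99-100),54 (43-65),100 (100-100)
h1_or_p2_gap8w_5y_exAB,adults,44,7390,25,41,1.1,64 (52-75),99 (99-100),52 (41-62),100 (100-100)
h1_or_p2_gap8w_2y_exA,adults,41,7402,28,29,0.9,59 (48-71),100 (100-100),59 (47-70),100 (100-100)
p1_rx_ever,seniors,53,3248,10,115,4.9,84 (75-93),97 (96-97),32 (25-39),100 (100-100)
p2_rx_ever,seniors,51,3318,12,45,2.8,81 (71-91),99 (98-99),53 (43-63),100 (99-100)
p2_gap60_rx_ever,seniors,49,3320,14,43,2.7,78 (68-88),99 (98-99),53 (43-64),100 (99-100)
h1_or_p2_rx_1y,seniors,52,3337,11,26,2.3,83 (73-92),99 (99-100),67 (56-77),100 (100-100)
h1_or_p2_rx_2y,seniors,52,3335,11,28,2.3,83 (73-92),99 (99-100),65 (55-76),100 (100-100)
h1_or_p2_rx_3y,seniors,52,3332,11,31,2.4,83 (73-92),99 (99-99),63 (52-73),100 (100-100)
h1_or_p2_spec_rx_1y,seniors,52,3347,11,16,2.0,83 (73-92),100 (99-100),77 (66-87),100 (100-100)
h1_or_p2_spec_rx_2y,seniors,52,3346,11,17,2.0,83 (73-92),100 (99-100),75 (65-86),100 (100-100)
h1_or_p2_spec_rx_3y,seniors,52,3345,11,18,2.0,83 (73-92),100 (99-100),74 (64-85),100 (100-100)
h1_or_p3_rx_1y,seniors,47,3346,16,17,1.9,75 (64-85),100 (99-100),73 (63-84),100 (99-100)
h1_or_p3_rx_2y,seniors,48,3342,15,21,2.0,76 (66-87),99 (99-100),70 (59-80),100 (99-100)
h1_or_p3_rx_3y,seniors,48,3342,15,21,2.0,76 (66-87),99 (99-100),70 (59-80),100 (99-100)
h1_or_p3_spec_rx_1y,seniors,47,3351,16,12,1.7,75 (64-85),100 (99-100),80 (69-90),100 (99-100)
h1_or_p3_spec_rx_2y,seniors,48,3349,15,14,1.8,76 (66-87),100 (99-100),77 (67-88),100 (99-100)
h1_or_p3_spec_rx_3y,seniors,48,3348,15,15,1.8,76 (66-87),100 (99-100),76 (66-87),100 (99-100)
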