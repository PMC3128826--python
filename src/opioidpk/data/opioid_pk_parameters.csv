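name,phase_label,t_half_h,t_half_min,k_e_per_h,k_e_per_min,v_d_l_per_kg,cl_l_per_h_per_kg,cl_l_per_min_per_kg,f_iv,f_oral,f_buccal,f_patch,f_oral_lo,f_oral_hi,k_a_per_h,k_a_per_min,window_min,window_max,analgesic_threshold
morphine,,3.9,,0.318,,4.5,1.43,,1.0,0.40,,,0.15,0.64,15.6,,10,80,20
tramadol,,5.5,,0.132,,2.8,0.37,,1.0,0.76,,,0.73,0.79,2.6,,,,
codeine,,2.6,,0.377,,3.0,1.23,,1.0,0.50,,,,,15.6,,,,
meperidine,,3.5,,0.242,,4.0,0.98,,1.0,0.50,,,0.40,0.60,4.8,,,,
hydrocodone,,6.1,,0.141,,4.0,0.61,,1.0,0.80,,,,,2.8,,,,
oxycodone IR,,4.5,,0.174,,2.8,0.42,,1.0,0.74,,,0.60,0.87,3.5,,,,
oxycodone CR,phase I,,33.5,,0.021,2.8,,0.06,1.0,0.74,,,0.60,0.87,,0.42,,,
oxycodone CR,phase II,4.6,,0.160,,2.8,0.58,,1.0,0.74,,,0.60,0.87,3.2,,,,
hydromorphone,,6.0,,0.154,,3.0,0.54,,1.0,0.55,,,0.52,0.58,3.1,,,,
oxymorphone,,8.0,,0.115,,3.0,0.40,,1.0,0.10,,,,,2.3,,,,
methadone,,35,,0.029,,5.5,0.19,,1.0,0.80,,,0.10,0.90,0.58,,,,
fentanyl,,7.5,,0.144,,5.5,1.32,,1.0,0.33,0.50,0.92,,,2.9,,,,
buprenorphine,,33.5,,0.026,,3.8,0.13,,1.0,0.63,,,0.50,0.75,0.52,,,,
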