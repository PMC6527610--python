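# label: ocular-media optical density components (two-part lens model, ages 20-60)
# columns: wavelength_nm, TL1 (age-varying portion), TL2 (stable portion)
wavelength_nm,TL1,TL2
400,0.600,1.000
410,0.510,0.583
420,0.433,0.300
430,0.377,0.116
440,0.327,0.033
450,0.295,0.005
460,0.267,0.000
470,0.233,0.000
480,0.207,0.000
490,0.187,0.000
500,0.167,0.000
510,0.147,0.000
520,0.133,0.000
530,0.120,0.000
540,0.107,0.000
550,0.093,0.000
560,0.080,0.000
570,0.067,0.000
580,0.053,0.000
590,0.040,0.000
600,0.033,0.000
610,0.027,0.000
620,0.020,0.000
630,0.013,0.000
640,0.007,0.000
650,0.000,0.000
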