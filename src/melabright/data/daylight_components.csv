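# label: CIE daylight characteristic vectors S0, S1, S2 (10 nm tabulation)
wavelength_nm,S0,S1,S2
300,0.04,0.02,0.00
310,6.00,4.50,2.00
320,29.60,22.40,4.00
330,55.30,42.00,8.50
340,57.30,40.60,7.80
350,61.80,41.60,6.70
360,61.50,38.00,5.30
370,68.80,42.40,6.10
380,63.40,38.50,3.00
390,65.80,35.00,1.20
400,94.80,43.40,-1.10
410,104.80,46.30,-0.50
420,105.90,43.90,-0.70
430,96.80,37.10,-1.20
440,113.90,36.70,-2.60
450,125.60,35.90,-2.90
460,125.50,32.60,-2.80
470,121.30,27.90,-2.60
480,121.30,24.30,-2.60
490,113.50,20.10,-1.80
500,113.10,16.20,-1.50
510,110.80,13.20,-1.30
520,106.50,8.60,-1.20
530,108.80,6.10,-1.00
540,105.30,4.20,-0.50
550,104.40,1.90,-0.30
560,100.00,0.00,0.00
570,96.00,-1.60,0.20
580,95.10,-3.50,0.50
590,89.10,-3.50,2.10
600,90.50,-5.80,3.20
610,90.30,-7.20,4.10
620,88.40,-8.60,4.70
630,84.00,-9.50,5.10
640,85.10,-10.90,6.70
650,81.90,-10.70,7.30
660,82.60,-12.00,8.60
670,84.90,-14.00,9.80
680,81.30,-13.60,10.20
690,71.90,-12.00,8.30
700,74.30,-13.30,9.60
710,76.40,-12.90,8.50
720,63.30,-10.60,7.00
730,71.70,-11.60,7.60
740,77.00,-12.20,8.00
750,65.20,-10.20,6.70
760,47.70,-7.80,5.20
770,68.60,-11.20,7.40
780,65.00,-10.40,6.80
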