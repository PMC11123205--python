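# Synthetic compilation of human hemoglobin molar extinction coefficients.
# Anchor values (cm^-1 / M, log base e NOT applied; multiply by ln(10) for
# absorption) approximating the widely used public-domain oxy/deoxy
# compilation at ~5-10 nm spacing; intended for interpolation (PCHIP) on
# 450-800 nm. Landmarks preserved: ~500/545/570/584/797 nm isosbestic
# points, HbO2 double peak (542/577 nm), Hb peak (555 nm), deep-red window
# (650-700 nm) where Hb >> HbO2, and the 758 nm Hb shoulder.
# This file is a constructed stand-in compiled from published landmark
# values, not a copy of any distributed table.
wavelength_nm,eps_hbo2_cm1_M,eps_hb_cm1_M
450,62816,103292
460,33209,72684
470,18649,43568
480,14550,28324
490,14677,21290
500,20932,20862
510,25154,21423
520,30885,25773
530,39956,35464
535,45513,41420
540,53236,46592
545,51516,51516
550,43016,52276
555,36068,55540
560,32613,53788
565,35212,50312
570,44496,45072
575,55540,40344
577,61014,38668
580,50104,36000
584,28324,28324
590,11352,17508
595,5860,16156
600,3200,14677
610,1506,11080
620,942,8554
630,610,5149
640,442,4345
650,368,3750
660,320,3227
670,294,2795
680,278,2408
690,276,2052
700,290,1794
710,314,1540
720,348,1327
730,390,1245
740,446,1116
750,518,1405
758,586,1669
770,650,1312
780,710,1075
790,768,904
800,816,762
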