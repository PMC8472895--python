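wavelength_nm,dose,mu_a,mu_s,mu_t
630,P-0,5.34,120.06,125.39
630,P-30,1.67,29.72,31.39
630,P-100,3.69,66.35,70.04
640,P-0,5.44,121.17,126.61
640,P-30,1.84,32.28,34.12
640,P-100,4.48,79.63,84.11
650,P-0,5.53,122.29,127.82
650,P-30,3.59,61.83,65.43
650,P-100,4.98,87.58,92.57
660,P-0,5.62,122.92,128.54
660,P-30,4.50,76.30,80.81
660,P-100,5.30,92.61,97.92
670,P-0,5.68,123.54,129.22
670,P-30,5.01,83.97,88.99
670,P-100,5.54,96.01,101.55
680,P-0,5.74,124.04,129.79
680,P-30,5.32,88.71,94.03
680,P-100,5.73,98.45,104.18
690,P-0,5.77,124.78,130.55
690,P-30,5.60,92.26,97.86
690,P-100,5.86,100.30,106.16
700,P-0,5.80,125.38,131.19
700,P-30,5.80,94.93,100.74
700,P-100,5.95,102.11,108.07
710,P-0,5.87,125.42,131.29
710,P-30,5.97,96.73,102.70
710,P-100,6.03,103.41,109.45
720,P-0,5.88,126.03,131.91
720,P-30,6.07,98.11,104.18
720,P-100,6.11,104.23,110.34
730,P-0,5.91,126.84,132.75
730,P-30,6.18,99.92,106.11
730,P-100,6.19,105.72,111.92
740,P-0,5.95,126.85,132.81
740,P-30,6.29,100.57,106.86
740,P-100,6.25,106.35,112.60
750,P-0,5.99,127.01,133.00
750,P-30,6.37,101.36,107.73
750,P-100,6.32,106.89,113.21
760,P-0,6.04,126.73,132.77
760,P-30,6.46,101.62,108.09
760,P-100,6.38,107.24,113.63
770,P-0,6.04,127.27,133.32
770,P-30,6.49,102.19,108.68
770,P-100,6.41,107.65,114.06
780,P-0,6.06,127.60,133.66
780,P-30,6.55,102.48,109.038
780,P-100,6.44,108.08,114.53
790,P-0,6.07,127.86,133.94
790,P-30,6.59,102.71,109.31
790,P-100,6.46,108.47,114.94
800,P-0,6.09,128.02,134.12
800,P-30,6.65,102.78,109.43
800,P-100,6.47,109.11,115.59
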