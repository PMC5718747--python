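# Energy-absorption buildup factors of water: ANSI/ANS-6.4.3 standard vs GP-method values (published reference values)
energy_MeV,depth_mfp,ansi,gp_method,percent_error_printed
0.15,1,3.91,3.84,1.84
0.3,1,2.84,2.87,1.14
0.5,1,2.45,2.47,0.85
0.15,2,9.36,9.37,0.07
0.3,2,6.25,6.24,0.16
0.5,2,4.87,4.84,0.71
0.15,3,18.60,18.30,1.62
0.3,3,11.50,11.34,1.43
0.5,3,8.29,8.12,2.08
0.15,4,32.50,31.60,2.76
0.3,4,19.00,18.49,2.66
0.5,4,12.70,12.40,2.38
0.15,5,52.00,50.39,3.09
0.3,5,28.80,28.07,2.54
0.5,5,18.10,17.76,1.90
0.15,6,77.90,75.87,2.60
0.3,6,41.20,40.41,1.91
0.5,6,24.60,24.26,1.37
0.15,7,111.00,109.33,1.50
0.3,7,56.50,55.86,1.13
0.5,7,32.20,31.97,0.73
0.15,8,153.00,152.10,0.59
0.3,8,75.00,74.73,0.36
0.5,8,40.80,40.91,0.26
0.15,10,268.00,270.97,1.11
0.3,10,122.00,123.82,1.49
0.5,10,61.80,62.57,1.25
0.15,15,805.00,825.45,2.54
0.3,15,318.00,322.26,1.34
0.5,15,137.00,138.40,1.02
0.15,20,1890.00,1897.57,0.40
0.3,20,656.00,647.46,1.30
0.5,20,247.00,244.31,1.09
0.15,25,3840.00,3804.69,0.92
0.3,25,1180.00,1148.35,2.68
0.5,25,395.00,386.69,2.10
0.15,30,7050.00,7158.55,1.54
0.3,30,1930.00,1916.63,0.69
0.5,30,582.00,579.99,0.34
0.15,35,12100.00,12619.08,4.29
0.3,35,2950.00,2992.81,1.45
0.5,35,809.00,822.03,1.61
0.15,40,19600.00,19968.27,1.88
0.3,40,4280.00,4205.56,1.74
0.5,40,1080.00,1067.38,1.17
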