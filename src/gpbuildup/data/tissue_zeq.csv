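# Equivalent atomic numbers Zeq of the twelve built-in tissues (published reference values)
energy_MeV,adipose_tissue,blood,cortical_bone,brain,breast_tissue,eye_lens,lung_tissue,skeletal_muscle,ovary,testis,soft_tissue,soft_tissue4
0.015,6.39,7.56,12.99,7.50,6.96,7.25,7.52,7.49,7.50,7.47,7.50,7.28
0.020,6.41,7.61,13.18,7.54,7.00,7.28,7.56,7.53,7.53,7.51,7.54,7.31
0.030,6.43,7.66,13.40,7.58,7.05,7.31,7.60,7.57,7.57,7.54,7.58,7.33
0.040,6.44,7.68,13.53,7.61,7.06,7.32,7.62,7.59,7.59,7.56,7.60,7.33
0.050,6.45,7.71,13.62,7.62,7.08,7.33,7.64,7.61,7.60,7.57,7.61,7.34
0.060,6.46,7.72,13.69,7.64,7.08,7.34,7.65,7.62,7.61,7.58,7.63,7.34
0.080,6.47,7.75,13.78,7.66,7.09,7.34,7.66,7.64,7.62,7.59,7.65,7.34
0.100,6.48,7.77,13.84,7.67,7.10,7.35,7.68,7.65,7.63,7.60,7.66,7.35
0.150,6.49,7.80,13.94,7.69,7.11,7.36,7.70,7.67,7.65,7.62,7.68,7.35
0.200,6.49,7.81,14.00,7.71,7.12,7.37,7.71,7.69,7.66,7.63,7.69,7.35
0.300,6.50,7.83,14.06,7.72,7.12,7.37,7.72,7.70,7.67,7.64,7.71,7.36
0.400,6.50,7.84,14.09,7.73,7.13,7.38,7.73,7.71,7.68,7.64,7.71,7.36
0.500,6.50,7.85,14.10,7.73,7.13,7.38,7.73,7.71,7.68,7.65,7.72,7.36
0.600,6.51,7.86,14.11,7.74,7.13,7.38,7.73,7.71,7.68,7.65,7.72,7.36
0.800,6.51,7.86,14.12,7.74,7.13,7.38,7.74,7.72,7.68,7.65,7.72,7.36
1.000,6.51,7.86,14.12,7.74,7.13,7.38,7.74,7.72,7.68,7.65,7.72,7.36
1.500,5.56,6.65,11.43,6.55,6.13,6.47,6.64,6.58,6.63,6.60,6.59,6.55
2.000,5.53,6.59,10.78,6.49,6.09,6.43,6.59,6.53,6.58,6.55,6.53,6.51
3.000,5.52,6.57,10.61,6.48,6.08,6.42,6.57,6.52,6.57,6.54,6.52,6.51
4.000,5.51,6.57,10.56,6.47,6.07,6.42,6.57,6.51,6.56,6.53,6.52,6.50
5.000,5.51,6.57,10.53,6.47,6.07,6.41,6.57,6.51,6.56,6.53,6.51,6.50
6.000,5.51,6.56,10.52,6.47,6.07,6.41,6.56,6.50,6.55,6.53,6.51,6.50
8.000,5.51,6.56,10.51,6.46,6.06,6.41,6.56,6.50,6.55,6.53,6.51,6.49
10.000,5.51,6.56,10.50,6.46,6.06,6.41,6.56,6.50,6.55,6.52,6.50,6.49
15.000,5.51,6.55,10.49,6.46,6.06,6.40,6.55,6.49,6.54,6.52,6.50,6.49
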