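population_id,n_individuals,CV_RH,CV_AGB,CV_LA,CV_SLA,CV_LDMC,CV_FvFm,CV_PI,CV_SPS,CV_SPI
KW,20,0.161,0.429,0.276,0.096,0.050,0.011,0.275,0.105,0.157
Bo,20,0.233,0.427,0.305,0.097,0.060,0.023,0.542,0.144,0.225
Ha,20,0.199,0.455,0.490,0.101,0.049,0.011,0.212,0.147,0.178
Wo,20,0.183,0.493,0.319,0.098,0.102,0.011,0.413,0.100,0.171
Ba,20,0.232,0.470,0.278,0.094,0.068,0.015,0.326,0.115,0.170
St,20,0.361,0.696,0.496,0.132,0.067,0.019,0.349,0.090,0.176
Sa,20,0.324,0.585,0.380,0.108,0.070,0.015,0.334,0.120,0.238
If,20,0.167,0.400,0.311,0.087,0.050,0.012,0.310,0.121,0.196
Ni,20,0.180,0.407,0.452,0.128,0.064,0.010,0.228,0.141,0.223
Di,20,0.172,0.457,0.312,0.121,0.062,0.021,0.458,0.079,0.135
Er,20,0.280,0.381,0.373,0.174,0.104,0.011,0.337,0.130,0.230
Gr,20,0.138,0.350,0.258,0.091,0.056,0.008,0.210,0.090,0.137
Eh,20,0.156,0.307,0.203,0.088,0.074,0.014,0.262,0.121,0.151
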