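population_id,location,date,latitude,longitude,iFD_CV,iFD_CV_se,HD,HD_se,GD,GD_se
KW,Riezlern,2015-07-17,47.361036,10.173825,0.173,0.044,0.143,0.044,0.597,0.083
Bo,Bottendorf,2016-05-22,51.316042,11.396525,0.228,0.058,0.303,0.091,0.612,0.072
Ha,Hardisleben,2016-05-25,51.162917,11.446789,0.205,0.055,0.235,0.056,0.630,0.098
Wo,Jena-Wogau,2016-05-29,50.924306,11.665083,0.210,0.054,0.257,0.064,0.654,0.080
Ba,Bad Frankenhausen,2016-05-31,51.367267,11.103056,0.196,0.048,0.244,0.054,0.666,0.060
St,Steinthaleben,2016-06-05,51.409550,11.004850,0.265,0.076,0.357,0.102,0.686,0.060
Sa,Saalfeld,2016-06-08,50.631003,11.383729,0.242,0.061,0.325,0.107,0.637,0.073
If,Ifta,2016-06-12,51.086633,10.148017,0.184,0.044,0.150,0.042,0.678,0.067
Ni,Niederwillingen,2016-06-15,50.776294,11.027711,0.204,0.049,0.169,0.053,0.661,0.085
Di,Dielsdorf,2016-06-19,51.095233,11.188406,0.202,0.056,0.295,0.111,0.647,0.072
Er,Erbenhausen,2016-06-23,50.565556,10.157383,0.224,0.043,0.346,0.097,0.658,0.078
Gr,Grossneundorf,2016-06-28,50.532456,11.294961,0.149,0.036,0.151,0.044,0.570,0.090
Eh,Ehrenberg,2016-06-29,50.478583,10.665786,0.153,0.031,0.193,0.064,0.595,0.084
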