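label,subset,chi,TE,NHD,LogS,I_shape,pic50_obs,pic50_pred_published
3a,train,3.69,-22284.29,1,-4.24,1,3.873,4.123
3c,train,3.32,-28517.24,1,-4.36,1,4.207,4.048
4a,train,3.55,-30624.97,0,-4.63,0,3.965,3.789
4b,train,3.33,-33741.52,0,-4.69,0,3.513,3.687
4c,train,3.26,-36857.93,0,-4.74,0,3.671,3.820
4d,train,3.26,-39974.39,0,-4.81,0,3.772,4.091
4e,train,3.28,-43090.46,0,-4.63,0,3.985,4.048
4f,train,3.65,-31695.02,0,-4.80,1,3.994,3.877
4g,train,3.35,-34811.42,0,-4.86,1,3.805,3.648
4h,train,3.28,-37927.91,0,-4.91,0,3.922,4.141
4i,train,3.30,-41044.32,0,-4.98,0,4.688,4.437
4j,train,3.33,-44160.43,0,-4.79,0,4.636,4.412
5b,train,3.34,-31601.86,1,-3.97,1,3.466,3.721
5d,train,3.32,-37834.79,1,-4.09,0,4.196,4.557
5e,train,3.34,-40950.81,1,-3.91,1,3.856,4.167
5g,train,3.43,-32671.91,1,-4.14,1,4.375,4.164
5h,train,3.34,-35788.34,1,-4.19,1,4.110,4.259
5i,train,3.34,-38904.72,1,-4.26,0,4.963,4.886
6a,train,3.70,-27944.84,1,-3.70,0,4.048,4.079
6b,train,3.51,-31061.38,1,-3.77,1,3.460,3.690
6c,train,3.15,-34177.67,1,-3.81,1,3.593,3.336
6e,train,3.19,-40410.15,1,-3.70,1,3.733,3.606
6f,train,3.62,-29014.79,1,-3.87,0,4.535,4.255
6g,train,3.37,-32131.27,1,-3.94,1,3.911,3.746
6h,train,3.29,-35247.71,1,-3.98,1,3.841,3.856
6i,train,3.28,-38364.13,1,-4.05,0,4.788,4.478
6j,train,3.30,-41480.16,1,-3.87,1,4.083,4.067
3b,test,3.42,-25400.81,1,-4.31,1,4.445,3.973
3e,test,3.32,-34749.71,1,-4.26,1,4.113,4.257
5a,test,3.67,-28485.40,1,-3.91,0,4.112,4.356
5c,test,3.32,-34718.32,1,-4.02,1,4.251,3.924
5j,test,3.35,-42020.78,1,-4.08,1,4.064,4.476
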