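label,subset,chi,TE,NHD,LogS,I_shape,pic50_obs,pic50_pred_published
Pred1,designed,3.59,-38488.55,1,-4.47,0,,5.56
Pred2,designed,3.75,-48294.76,1,-4.88,0,,6.95
Pred3,designed,3.75,-38072.44,1,-4.68,0,,6.09
Pred4,designed,3.56,-38072.37,1,-4.69,1,,5.43
Pred5,designed,3.91,-37656.22,1,-4.90,0,,6.62
Pred6,designed,3.46,-105753.16,1,-5.01,0,,9.91
Pred7,designed,3.67,-36349.39,3,-4.23,0,,8.21
Pred8,designed,3.72,-41749.65,3,-4.70,0,,9.24
Pred9,designed,3.86,-42061.89,1,-4.77,0,,6.62
Pred10,designed,3.51,-35372.05,1,-4.41,1,,4.81
Pred11,designed,4.02,-35754.97,1,-4.06,0,,5.54
Pred12,designed,3.92,-41571.56,1,-4.33,0,,6.08
Pred13,designed,3.88,-44687.87,1,-4.16,0,,5.97
Pred14,designed,3.45,-41604.75,1,-4.25,1,,4.86
Pred15,designed,3.51,-35372.05,1,-4.39,1,,4.79
Pred16,designed,2.90,-46999.25,2,-4.76,1,,6.43
Pred17,designed,3.30,-51410.93,1,-4.94,0,,6.48
Pred18,designed,2.98,-40411.16,2,-4.06,0,,5.61
Pred19,designed,3.14,-40411.30,2,-4.11,0,,5.93
Pred20,designed,3.17,-40411.17,2,-4.06,0,,5.91
Pred21,designed,3.14,-35684.73,3,-3.86,1,,6.44
Pred22,designed,3.03,-34074.65,4,-3.66,0,,7.74
Pred23,designed,3.21,-34074.57,4,-3.60,0,,7.96
Pred24,designed,3.07,-35580.95,5,-3.19,0,,8.73
Pred25,designed,3.04,-37087.31,6,-2.77,0,,9.68
Pred26,designed,3.42,-39994.98,2,-4.29,0,,6.61
Pred27,designed,3.81,-43131.76,1,-5.13,0,,7.10
Pred28,designed,3.89,-42641.58,1,-4.53,0,,6.38
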