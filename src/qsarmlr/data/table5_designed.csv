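compound_id,AATS7s,MATS2c,SpMin3_Bhi,MDEC-33,predicted_pIC50
a,4.65426,-0.08643,1.422487,8.99956,8.007063
b,4.887336,-0.06669,1.422521,13.38021,8.982861
c,4.686847,-0.06804,1.473045,15.7691,9.167553
d,4.620868,-0.0867,1.422633,15.7691,9.660035
e,4.385983,-0.08759,1.472606,11.30879,8.180639
f,4.254474,0.042657,1.415929,11.30879,8.18336
g,5.166064,-0.07107,1.420907,8.99956,7.921204
h,4.912833,-0.01094,1.478859,11.30879,7.803298
i,4.755541,-0.09143,1.421056,11.30879,8.591879
j,5.677675,-0.05352,1.422787,11.1857,8.331555
k,5.329807,-0.05452,1.473214,13.54342,8.520435
l,4.755541,-0.09143,1.421056,11.30879,8.591879
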