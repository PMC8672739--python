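ga_weeks,sex,measure,grams
22,female,bw_p10,380
22,male,bw_p10,420
23,female,bw_p10,461
23,male,bw_p10,501
24,female,bw_p10,542
24,male,bw_p10,582
25,female,bw_p10,628
25,male,bw_p10,668
26,female,bw_p10,687
26,male,bw_p10,727
27,female,bw_p10,742
27,male,bw_p10,782
28,female,bw_p10,802
28,male,bw_p10,842
29,female,bw_p10,885
29,male,bw_p10,925
30,female,bw_p10,965
30,male,bw_p10,1005
31,female,bw_p10,1036
31,male,bw_p10,1076
32,female,bw_p10,1100
32,male,bw_p10,1140
33,female,bw_p10,1159
33,male,bw_p10,1199
34,female,bw_p10,1249
34,male,bw_p10,1289
35,female,bw_p10,1334
35,male,bw_p10,1374
36,female,bw_p10,1421
36,male,bw_p10,1461
37,female,bw_p10,1508
37,male,bw_p10,1548
38,female,bw_p10,1566
38,male,bw_p10,1606
39,female,bw_p10,1660
39,male,bw_p10,1700
40,female,bw_p10,1714
40,male,bw_p10,1754
41,female,bw_p10,1775
41,male,bw_p10,1815
42,female,bw_p10,1823
42,male,bw_p10,1863
22,any,placenta_mean,150
23,any,placenta_mean,164
24,any,placenta_mean,174
25,any,placenta_mean,189
26,any,placenta_mean,200
27,any,placenta_mean,211
28,any,placenta_mean,226
29,any,placenta_mean,241
30,any,placenta_mean,253
31,any,placenta_mean,267
32,any,placenta_mean,281
33,any,placenta_mean,303
34,any,placenta_mean,313
35,any,placenta_mean,325
36,any,placenta_mean,343
37,any,placenta_mean,360
38,any,placenta_mean,377
39,any,placenta_mean,392
40,any,placenta_mean,404
41,any,placenta_mean,414
42,any,placenta_mean,428
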