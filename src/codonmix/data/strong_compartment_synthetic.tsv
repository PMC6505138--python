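# source: synthetic
rank	frequency
1	0.08142101540687462
2	0.07482127814686376
3	0.06875649530474509
4	0.06318330511959575
5	0.05806186060156012
6	0.05335554463530999
7	0.04903070817634221
8	0.04505642966828024
9	0.041404293961069434
10	0.03804818914938416
11	0.034964119878689096
12	0.032130035784137416
13	0.0295256738356846
14	0.02713241346222281
15	0.02493314341890752
16	0.022912139445809623
17	0.02105495184318109
18	0.019348302159524062
19	0.017779988253807555
20	0.016338797053049064
21	0.015014424381498484
22	0.013797401288221945
23	0.012679026346345308
24	0.011651303439912858
25	0.010706884593552056
26	0.009839017436189937
27	0.009041496923199175
28	0.008308620971798637
29	0.007635149692511973
30	0.007016267925198896
31	0.006447550811800621
32	0.005924932159652725
33	0.005444675369170656
34	0.005003346718047683
35	0.004597790810953647
36	0.004225108019205705
37	0.003882633749109973
38	0.003567919390747732
39	0.0032787148109944203
40	0.003012952265600737
41	0.0027687316153109797
42	0.002544306740317402
43	0.0023380730559171494
44	0.002148556040111657
45	0.0019744006911235996
46	0.0018143618394550977
47	0.001667295245220722
48	0.001532149417103316
49	0.001407958094440114
50	0.0012938333386878576
51	0.0011889591848725084
52	0.0010925858076329428
53	0.0010040241601472074
54	0.0009226410476109426
55	0.0008478546000444922
56	0.0007791301120603645
57	0.0007159762198463521
58	0.0006579413880306491
59	0.0006046106813108886
60	0.0005556027977650012
61	0.000510567342632783
62	0.00046918232307634796
63	0.00043115184600759835
64	0.0003962040025227263
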