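# Australian-style life table (SYNTHETIC).
# Generated by bchicea.lifetables.synthetic_life_table from Gompertz-Makeham
# hazards calibrated to published Australian adult mortality summaries
# (q40 ~ 0.76 / 1.34 per 1000 for females / males; life expectancy at birth
# ~85 / ~81 years). This is a synthetic stand-in, not official national
# statistics; supply your own table in the same format for registry-grade
# analyses.
# columns: age (integer years), sex (female|male), q_annual (annual death
# probability); terminal age 100 is absorbing (q_annual = 1).
age	sex	q_annual
0	female	0.00021309
1	female	0.000214397
2	female	0.000215834
3	female	0.000217414
4	female	0.000219151
5	female	0.000221061
6	female	0.000223162
7	female	0.000225473
8	female	0.000228013
9	female	0.000230807
10	female	0.000233879
11	female	0.000237257
12	female	0.000240972
13	female	0.000245057
14	female	0.00024955
15	female	0.00025449
16	female	0.000259922
17	female	0.000265895
18	female	0.000272464
19	female	0.000279688
20	female	0.000287631
21	female	0.000296366
22	female	0.000305971
23	female	0.000316533
24	female	0.000328148
25	female	0.00034092
26	female	0.000354965
27	female	0.000370409
28	female	0.000387392
29	female	0.000406068
30	female	0.000426604
31	female	0.000449186
32	female	0.000474018
33	female	0.000501324
34	female	0.000531351
35	female	0.000564369
36	female	0.000600676
37	female	0.000640601
38	female	0.000684502
39	female	0.000732776
40	female	0.000785858
41	female	0.000844227
42	female	0.000908409
43	female	0.000978983
44	female	0.00105658
45	female	0.00114191
46	female	0.00123574
47	female	0.0013389
48	female	0.00145233
49	female	0.00157705
50	female	0.00171419
51	female	0.00186497
52	female	0.00203074
53	female	0.00221301
54	female	0.00241341
55	female	0.00263372
56	female	0.00287594
57	female	0.00314223
58	female	0.00343498
59	female	0.0037568
60	female	0.00411058
61	female	0.00449947
62	female	0.00492693
63	female	0.00539679
64	female	0.00591321
65	female	0.0064808
66	female	0.00710457
67	female	0.00779006
68	female	0.00854331
69	female	0.00937097
70	female	0.0102803
71	female	0.0112793
72	female	0.0123767
73	female	0.0135821
74	female	0.0149059
75	female	0.0163596
76	female	0.0179556
77	female	0.0197078
78	female	0.0216309
79	female	0.0237413
80	female	0.0260569
81	female	0.0285968
82	female	0.0313822
83	female	0.034436
84	female	0.037783
85	female	0.0414502
86	female	0.0454667
87	female	0.0498641
88	female	0.0546763
89	female	0.05994
90	female	0.0656944
91	female	0.0719816
92	female	0.0788466
93	female	0.0863371
94	female	0.0945038
95	female	0.1034
96	female	0.113082
97	female	0.123609
98	female	0.13504
99	female	0.147438
100	female	1
0	male	0.00032439
1	male	0.000326825
2	male	0.000329503
3	male	0.000332448
4	male	0.000335686
5	male	0.000339247
6	male	0.000343162
7	male	0.000347468
8	male	0.000352203
9	male	0.00035741
10	male	0.000363136
11	male	0.000369432
12	male	0.000376356
13	male	0.000383969
14	male	0.000392342
15	male	0.000401548
16	male	0.000411673
17	male	0.000422805
18	male	0.000435048
19	male	0.00044851
20	male	0.000463314
21	male	0.000479592
22	male	0.000497493
23	male	0.000517177
24	male	0.000538823
25	male	0.000562625
26	male	0.000588798
27	male	0.00061758
28	male	0.000649228
29	male	0.00068403
30	male	0.000722298
31	male	0.000764379
32	male	0.000810651
33	male	0.000861532
34	male	0.000917481
35	male	0.000979002
36	male	0.00104665
37	male	0.00112103
38	male	0.00120282
39	male	0.00129276
40	male	0.00139165
41	male	0.00150038
42	male	0.00161993
43	male	0.00175138
44	male	0.00189591
45	male	0.00205483
46	male	0.00222955
47	male	0.00242164
48	male	0.00263284
49	male	0.00286504
50	male	0.00312031
51	male	0.00340094
52	male	0.00370946
53	male	0.00404861
54	male	0.00442142
55	male	0.00483123
56	male	0.00528169
57	male	0.0057768
58	male	0.00632097
59	male	0.00691902
60	male	0.00757626
61	male	0.0082985
62	male	0.00909212
63	male	0.00996408
64	male	0.0109221
65	male	0.0119744
66	male	0.0131304
67	male	0.0144
68	male	0.0157943
69	male	0.0173252
70	male	0.019006
71	male	0.0208509
72	male	0.0228757
73	male	0.0250974
74	male	0.0275348
75	male	0.0302079
76	male	0.0331391
77	male	0.0363521
78	male	0.039873
79	male	0.0437299
80	male	0.0479533
81	male	0.0525761
82	male	0.0576337
83	male	0.0631641
84	male	0.0692083
85	male	0.0758098
86	male	0.0830151
87	male	0.0908737
88	male	0.0994377
89	male	0.108762
90	male	0.118904
91	male	0.129924
92	male	0.141883
93	male	0.154844
94	male	0.168871
95	male	0.184028
96	male	0.200375
97	male	0.217975
98	male	0.236881
99	male	0.257144
100	male	1
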