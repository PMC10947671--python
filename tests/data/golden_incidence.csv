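id,T,Y,C_T,C_2T,m_star,D0,D1,D2
 1,13,1;13;2;3;3;1;1;1;1;4,0.838709677419355,0.894686850252988, 8.57668711656442, 8.15059419108499, 5.66639831364136, 4.09615268772041
 2,18,6;4;3;10;10;4;11;8;2;10;4;7,1.000000000000000,1.000000000000000, 3.40100402321359, 8.95495120087888, 8.15403516554037, 7.48109985538063
 3,26,26;5;1;5;16;3;5;4;9;3,1.000000000000000,1.000000000000000, 4.40067750677507, 6.36102159328830, 5.31180104722693, 4.56893491703627
 4,13,4;13;1;1;7;7;1;2;6,0.932330827067669,0.966492916924108, 2.96052631578947, 5.52318733897681, 4.97061121194811, 4.54009159999546
 5,12,1;5;12;1;4,0.926421404682274,0.990088406396902, 2.88095238095238, 3.02738095238095, 2.71045889282554, 2.48266629709101
 6,11,5;1;4;4;3;10;1;1;1;3;1;4,0.874686716791980,0.926731918660847, 4.92250000000000, 8.81502705627706, 7.50352094443483, 6.45967359116617
 7,13,1;4;1;4;1;2;13;13;8;1,0.920000000000000,0.952943890637074, 2.70664928292047, 5.47008597660488, 4.95450439875130, 4.59182408681036
 8,22,1;6;3;13;3;12;10;6;4;9;6;1;9;3;7,0.980364656381487,0.997346307496528, 4.39257498507189,10.48148135249536, 9.37480476486042, 8.46456671955533
 9,18,9;1;1;18;1;6;10;1,0.918105178643115,0.959021698182034, 2.56175972927242, 3.94908375081561, 3.61991017735948, 3.36860733295018
10,20,1;1;14;1,0.832352941176471,0.939900889478568, 2.88175824175824, 1.40745941777521, 1.28306553933371, 1.18571469659659
11,20,10;19;6;9;1;9;1;3;5,0.971277399848828,0.996119301731879, 3.10844868735084, 5.66089848304603, 5.08449164341379, 4.62671516943612
12,17,3;1;4;17;7;2;11;3;7;1,0.966386554621849,0.988007186731217, 3.61067174845164, 6.27586717964937, 5.47144720586418, 4.87317893312474
13, 8,3;4;1;3;1;2;3;1;8;2;8,0.930000000000000,0.982648687622423, 3.50649350649351, 8.32996289424861, 7.22543702432810, 6.41587421529877
14,29,8;9;15;1;10;12;26;4;19,1.000000000000000,1.000000000000000, 2.72229237493929, 5.94527253360299, 5.44735504959280, 5.04233462735162
15, 6,2;1;4;3;6;1;1;5;1;1,0.814814814814815,0.883301920947573, 5.00000000000000, 9.16666666666667, 7.48710619437210, 6.43004115226337
16,30,1;8;16;6;8;21,1.000000000000000,1.000000000000000, 3.30527203237410, 3.86625610861885, 3.49638928176479, 3.19388385379209
17,21,2;13;1;1;14;11;1;1;7;7;1;1;3,0.906323185011710,0.933796364464348, 4.28464797524338, 6.77510911465290, 5.95509054169382, 5.32865273000146
18,20,3;20;2;7;3;9;2;1;15;12;12;11;6;8,0.992557775166471,0.999836988559635, 2.65769466584917, 8.94320178127723, 8.20046613207402, 7.60419338037157
19,19,1;1;5;4;1;5;5;1;18;17;3;3;1;6,0.931480776551199,0.959287554554295, 4.88083187171135, 8.57454786685936, 6.97024845335011, 5.87715969188324
20, 5,2;5;1;1;1;1;2,0.753846153846154,0.919340307692308, 5.93051922654877, 7.60000000000000, 5.98409301872422, 4.70730119593294
21,22,3;12;1;11;12;3;1;1;15;2;6;17;4;1,0.956101384896786,0.973840515259383, 3.31446215139442, 7.63431796259936, 6.87761960716668, 6.27592142160530
22,22,9;11;6;6;18,1.000000000000000,1.000000000000000, 2.69292821949570, 3.78751300144161, 3.48157426501908, 3.22874738503842
23,11,1;1;2;1;1;2;1;3;1;11;1;4;1;2;1,0.744318181818182,0.874285930164101,14.80573342613025,17.67272727272727,11.11978366813593, 6.72380246647928
24,14,6;3;2;7;4;6;2;4;2;4;6;11,1.000000000000000,1.000000000000000, 3.94988679245283, 9.25612847529829, 8.27485243570636, 7.45878181278134
25, 6,1;1;3;3;2;3;1;6;1;3;1;3;4;3;1,0.843750000000000,0.893916537985206, 3.63636363636364,12.41212121212121,11.09508148920334,10.01069518716578
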