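serial,sample_id,shred_1,shred_2,area_sum,aar,car
1,GY-1,G-1,Y-2,16602.0,0.771,0.789
2,GY-2,G-2,Y-4,17935.5,0.933,1.05
3,GY-3,G-4,Y-1,16424,0.922,1
4,GY-4,G-5,Y-2,20179,0.842,0.898
5,GZ-1,G-4,Z-5,16519.5,0.846,0.952
6,GZ-2,G-2,Z-5,16399,0.8,0.884
7,GZ-3,G-1,Z-4,13114.5,0.842,1
8,GZ-4,G-2,Z-1,16997.5,0.795,0.901
9,PG-1,P-4,G-1,12511,0.758,0.857
10,PG-2,P-3,G-4,14812,0.844,0.956
11,PG-3,P-5,G-3,13637,0.844,0.935
12,PG-4,P-2,G-2,16920,0.684,0.81
13,PY-1,P-4,Y-4,13104,0.849,0.916
14,PY-2,P-3,Y-1,11610,0.748,0.799
15,PY-3,P-5,Y-3,16025,0.825,0.947
16,PY-4,P-2,Y-2,16179.5,0.757,0.804
17,PZ-1,P-4,Z-3,13454.5,0.886,0.983
18,PZ-2,P-3,Z-1,12304,0.772,0.852
19,PZ-3,P-5,Z-5,12984,0.719,0.814
20,PZ-4,P-2,Z-2,12517,0.715,0.806
21,YZ-1,Y-2,Z-3,17545.5,0.742,0.802
22,YZ-2,Y-4,Z-5,14949.5,0.871,0.964
23,YZ-3,Y-1,Z-5,13317.5,0.866,0.955
24,YZ-4,Y-2,Z-3,17545.5,0.867,0.917
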