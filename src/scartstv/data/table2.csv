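patient_id,gtv_cc,band,arm,percent
1,2136.8,1500-3000,manual,59.9
1,2136.8,1500-3000,auto,74.06
1,2136.8,3000-4500,manual,15.4
1,2136.8,3000-4500,auto,12.86
1,2136.8,4500-5400,manual,6.9
1,2136.8,4500-5400,auto,3.87
1,2136.8,>5400,manual,9.1
1,2136.8,>5400,auto,8.5
2,909.7,1500-3000,manual,67.4
2,909.7,1500-3000,auto,72.8
2,909.7,3000-4500,manual,12.9
2,909.7,3000-4500,auto,13.5
2,909.7,4500-5400,manual,4.7
2,909.7,4500-5400,auto,4.98
2,909.7,>5400,manual,7.8
2,909.7,>5400,auto,7.43
3,876.6,1500-3000,manual,52.1
3,876.6,1500-3000,auto,61.05
3,876.6,3000-4500,manual,12.8
3,876.6,3000-4500,auto,11.57
3,876.6,4500-5400,manual,6
3,876.6,4500-5400,auto,3.72
3,876.6,>5400,manual,6.1
3,876.6,>5400,auto,8.12
4,1082.2,1500-3000,manual,44.3
4,1082.2,1500-3000,auto,58.02
4,1082.2,3000-4500,manual,9.3
4,1082.2,3000-4500,auto,11.69
4,1082.2,4500-5400,manual,3.5
4,1082.2,4500-5400,auto,4.07
4,1082.2,>5400,manual,4.7
4,1082.2,>5400,auto,6.56
5,125.6,1500-3000,manual,57.8
5,125.6,1500-3000,auto,61.15
5,125.6,3000-4500,manual,17.2
5,125.6,3000-4500,auto,13.46
5,125.6,4500-5400,manual,8.3
5,125.6,4500-5400,auto,4.7
5,125.6,>5400,manual,6.2
5,125.6,>5400,auto,8.04
6,183.6,1500-3000,manual,62.6
6,183.6,1500-3000,auto,69.17
6,183.6,3000-4500,manual,17.2
6,183.6,3000-4500,auto,14.38
6,183.6,4500-5400,manual,9.6
6,183.6,4500-5400,auto,4.85
6,183.6,>5400,manual,6.3
6,183.6,>5400,auto,8.99
7,961.5,1500-3000,manual,57.5
7,961.5,1500-3000,auto,61.56
7,961.5,3000-4500,manual,11.3
7,961.5,3000-4500,auto,11.88
7,961.5,4500-5400,manual,4.6
7,961.5,4500-5400,auto,4.24
7,961.5,>5400,manual,5.8
7,961.5,>5400,auto,7.33
8,637.6,1500-3000,manual,59.1
8,637.6,1500-3000,auto,63.68
8,637.6,3000-4500,manual,14.8
8,637.6,3000-4500,auto,12.26
8,637.6,4500-5400,manual,5.8
8,637.6,4500-5400,auto,4.27
8,637.6,>5400,manual,8.3
8,637.6,>5400,auto,7.75
9,373.9,1500-3000,manual,52.1
9,373.9,1500-3000,auto,59.29
9,373.9,3000-4500,manual,11.7
9,373.9,3000-4500,auto,11.69
9,373.9,4500-5400,manual,4.5
9,373.9,4500-5400,auto,3.85
9,373.9,>5400,manual,7.3
9,373.9,>5400,auto,8.1
10,1837.4,1500-3000,manual,52.9
10,1837.4,1500-3000,auto,63.25
10,1837.4,3000-4500,manual,9.6
10,1837.4,3000-4500,auto,11.56
10,1837.4,4500-5400,manual,4.4
10,1837.4,4500-5400,auto,4.27
10,1837.4,>5400,manual,4.6
10,1837.4,>5400,auto,7.11
11,1155,1500-3000,manual,44.5
11,1155,1500-3000,auto,63.01
11,1155,3000-4500,manual,10.3
11,1155,3000-4500,auto,11.98
11,1155,4500-5400,manual,3.8
11,1155,4500-5400,auto,4.23
11,1155,>5400,manual,6.5
11,1155,>5400,auto,7.75
12,961.4,1500-3000,manual,64.5
12,961.4,1500-3000,auto,60.77
12,961.4,3000-4500,manual,19
12,961.4,3000-4500,auto,11.86
12,961.4,4500-5400,manual,6.3
12,961.4,4500-5400,auto,3.98
12,961.4,>5400,manual,9.5
12,961.4,>5400,auto,7.66
13,1587.8,1500-3000,manual,70.2
13,1587.8,1500-3000,auto,73.28
13,1587.8,3000-4500,manual,14.4
13,1587.8,3000-4500,auto,13.07
13,1587.8,4500-5400,manual,5.3
13,1587.8,4500-5400,auto,3.93
13,1587.8,>5400,manual,7.9
13,1587.8,>5400,auto,8.57
14,2370.3,1500-3000,manual,46.1
14,2370.3,1500-3000,auto,61.94
14,2370.3,3000-4500,manual,10.1
14,2370.3,3000-4500,auto,11.66
14,2370.3,4500-5400,manual,5
14,2370.3,4500-5400,auto,3.92
14,2370.3,>5400,manual,4.7
14,2370.3,>5400,auto,7.28
15,312.6,1500-3000,manual,68.4
15,312.6,1500-3000,auto,62.83
15,312.6,3000-4500,manual,13.8
15,312.6,3000-4500,auto,12.83
15,312.6,4500-5400,manual,4.7
15,312.6,4500-5400,auto,4.22
15,312.6,>5400,manual,7.5
15,312.6,>5400,auto,8.48
16,218.6,1500-3000,manual,61.5
16,218.6,1500-3000,auto,64.36
16,218.6,3000-4500,manual,13.1
16,218.6,3000-4500,auto,14.27
16,218.6,4500-5400,manual,4
16,218.6,4500-5400,auto,4.99
16,218.6,>5400,manual,7.2
16,218.6,>5400,auto,7.64
17,928.2,1500-3000,manual,54.9
17,928.2,1500-3000,auto,61.95
17,928.2,3000-4500,manual,9.3
17,928.2,3000-4500,auto,11.85
17,928.2,4500-5400,manual,3.2
17,928.2,4500-5400,auto,4.07
17,928.2,>5400,manual,5.2
17,928.2,>5400,auto,7.4
18,1979.6,1500-3000,manual,58.5
18,1979.6,1500-3000,auto,60.79
18,1979.6,3000-4500,manual,12.6
18,1979.6,3000-4500,auto,11.88
18,1979.6,4500-5400,manual,5.1
18,1979.6,4500-5400,auto,4.3
18,1979.6,>5400,manual,6.3
18,1979.6,>5400,auto,6.8
19,643.6,1500-3000,manual,69.5
19,643.6,1500-3000,auto,70.96
19,643.6,3000-4500,manual,15.2
19,643.6,3000-4500,auto,13.25
19,643.6,4500-5400,manual,6.2
19,643.6,4500-5400,auto,4.24
19,643.6,>5400,manual,7.3
19,643.6,>5400,auto,8.86
20,319.6,1500-3000,manual,62.1
20,319.6,1500-3000,auto,59.51
20,319.6,3000-4500,manual,16.5
20,319.6,3000-4500,auto,12.98
20,319.6,4500-5400,manual,7.1
20,319.6,4500-5400,auto,5.04
20,319.6,>5400,manual,5.3
20,319.6,>5400,auto,7.63
21,157,1500-3000,manual,62.4
21,157,1500-3000,auto,61.66
21,157,3000-4500,manual,17
21,157,3000-4500,auto,13.69
21,157,4500-5400,manual,6.2
21,157,4500-5400,auto,4.78
21,157,>5400,manual,9.2
21,157,>5400,auto,7.9
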