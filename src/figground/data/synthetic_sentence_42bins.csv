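bin,f1_hz,f2_hz,f3_hz
0,532.7,1113.6,3048.6
1,567.9,1142.6,3036.8
2,579.6,1190.6,3007.0
3,596.9,1236.7,2955.2
4,641.9,1265.5,2879.7
5,703.4,1250.5,2775.4
6,758.3,1206.3,2653.0
7,785.8,1181.5,2550.8
8,766.5,1197.0,2473.0
9,675.1,1265.6,2420.8
10,524.6,1418.5,2401.9
11,416.2,1640.7,2414.3
12,372.6,1840.9,2449.8
13,363.9,1963.5,2497.8
14,378.5,2004.0,2545.6
15,409.6,1974.1,2573.3
16,440.0,1893.7,2576.2
17,463.0,1777.3,2560.9
18,488.7,1643.3,2537.6
19,517.7,1543.5,2517.5
20,535.8,1506.2,2506.4
21,540.6,1510.3,2505.5
22,543.4,1490.4,2518.8
23,549.2,1421.2,2548.9
24,566.9,1347.5,2592.3
25,589.1,1271.6,2660.7
26,609.7,1200.5,2740.1
27,619.9,1164.5,2805.3
28,595.7,1171.9,2856.4
29,541.5,1215.0,2897.5
30,492.1,1286.0,2930.5
31,465.8,1379.1,2948.1
32,465.7,1504.6,2949.9
33,487.4,1630.7,2934.5
34,514.2,1702.2,2897.9
35,556.5,1721.6,2850.4
36,622.9,1701.3,2824.0
37,693.3,1674.2,2824.3
38,756.0,1652.5,2854.4
39,807.7,1629.3,2901.1
40,840.0,1593.3,2921.2
41,853.0,1534.8,2905.3
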