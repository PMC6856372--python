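bin,f1_hz,f2_hz,f3_hz
0,518.6,1605.2,2832.6
1,507.6,1763.8,2839.0
2,517.4,1828.4,2841.1
3,533.7,1808.0,2800.5
4,549.7,1743.8,2726.0
5,560.5,1632.8,2673.7
6,567.1,1502.4,2663.8
7,574.2,1401.2,2677.4
8,579.5,1344.3,2680.1
9,575.0,1334.1,2658.7
10,572.0,1355.2,2631.9
11,572.0,1388.4,2615.8
12,552.9,1419.3,2604.9
13,513.5,1441.1,2609.5
14,468.1,1435.5,2646.0
15,427.1,1424.7,2719.5
16,394.8,1430.4,2818.3
17,372.5,1456.8,2897.9
18,358.9,1510.0,2927.6
19,351.1,1571.3,2914.7
20,346.7,1628.9,2886.8
21,348.5,1681.5,2859.6
22,362.7,1755.7,2845.6
23,390.8,1827.4,2851.4
24,426.0,1856.5,2857.5
25,466.3,1847.0,2830.8
26,506.7,1806.3,2756.2
27,535.2,1726.0,2664.9
28,555.7,1615.2,2621.3
29,579.7,1513.7,2647.6
30,600.4,1447.2,2712.2
31,601.5,1438.6,2780.5
32,582.0,1446.5,2835.8
33,563.3,1440.3,2842.9
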