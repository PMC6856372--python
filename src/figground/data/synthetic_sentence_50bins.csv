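bin,f1_hz,f2_hz,f3_hz
0,563.0,1539.1,2411.0
1,616.1,1518.5,2425.1
2,643.2,1477.7,2463.2
3,636.0,1445.3,2544.6
4,590.9,1441.0,2669.8
5,528.1,1476.4,2777.4
6,481.9,1540.9,2819.8
7,458.5,1618.9,2810.7
8,455.4,1643.8,2781.4
9,464.8,1584.7,2741.4
10,473.0,1491.4,2724.5
11,474.2,1400.6,2781.3
12,476.7,1316.3,2895.7
13,474.3,1264.5,2985.3
14,459.8,1279.2,3015.4
15,445.6,1356.3,2993.5
16,438.3,1456.2,2922.8
17,437.8,1545.2,2813.8
18,442.4,1618.2,2685.1
19,456.1,1652.6,2582.9
20,477.7,1623.2,2539.4
21,502.4,1566.6,2533.4
22,528.4,1525.3,2544.2
23,552.2,1494.1,2558.0
24,579.1,1443.6,2563.4
25,597.6,1386.0,2565.9
26,599.3,1357.2,2578.7
27,610.4,1360.5,2607.6
28,639.7,1388.8,2640.8
29,657.9,1465.7,2668.9
30,655.8,1589.5,2676.7
31,635.3,1697.3,2668.9
32,592.8,1739.4,2676.4
33,538.1,1699.9,2692.7
34,490.1,1564.5,2677.0
35,467.5,1372.3,2618.8
36,468.5,1217.0,2536.7
37,478.9,1146.6,2452.3
38,498.1,1155.2,2397.6
39,525.1,1226.9,2380.8
40,548.9,1357.9,2400.3
41,571.9,1517.9,2461.3
42,590.8,1630.8,2549.8
43,610.6,1642.8,2645.0
44,630.7,1565.6,2737.8
45,634.2,1457.5,2813.0
46,621.0,1373.6,2854.3
47,591.8,1326.1,2883.6
48,553.9,1305.1,2938.7
49,532.0,1314.1,3001.1
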