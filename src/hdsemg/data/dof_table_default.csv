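movement_code,name,d2_flex,d2_ext,d3_flex,d3_ext,d4_flex,d4_ext,d5_flex,d5_ext,thumb_flex,thumb_ext,thumb_abd,thumb_add,wrist_flex,wrist_ext,wrist_pron,wrist_sup,provenance
1,basis: d2_flex,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,paper-stated
2,basis: d2_ext,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,paper-stated
3,basis: d3_flex,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,paper-stated
4,basis: d3_ext,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,paper-stated
5,basis: d4_flex,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,paper-stated
6,basis: d4_ext,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,paper-stated
7,basis: d5_flex,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,paper-stated
8,basis: d5_ext,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,paper-stated
9,basis: thumb_flex,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,paper-stated
10,basis: thumb_ext,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,paper-stated
11,basis: thumb_abd,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,paper-stated
12,basis: thumb_add,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,paper-stated
13,basis: wrist_flex,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,paper-stated
14,basis: wrist_ext,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,paper-stated
15,basis: wrist_pron,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,paper-stated
16,basis: wrist_sup,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,paper-stated
17,index + middle bend,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,user-supplied
18,middle + ring bend,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,user-supplied
19,ring + little bend,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,user-supplied
20,index + middle + ring bend,1,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,user-supplied
21,middle + ring + little bend,0,0,1,0,1,0,1,0,0,0,0,0,0,0,0,0,user-supplied
22,four-finger bend,1,0,1,0,1,0,1,0,0,0,0,0,0,0,0,0,user-supplied
23,thumb + index pinch,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,user-supplied
24,three-jaw chuck,1,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,user-supplied
25,power grip,1,0,1,0,1,0,1,0,1,0,0,0,0,0,0,0,user-supplied
26,thumb abduct + index bend,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,user-supplied
27,thumb adduct + index bend,1,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,user-supplied
28,pointing,0,1,1,0,1,0,1,0,0,0,0,0,0,0,0,0,user-supplied
29,hook grip + wrist stretch,1,0,1,0,1,0,1,0,0,0,0,0,0,1,0,0,user-supplied
30,index bend + wrist bend,1,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,user-supplied
31,ring bend + wrist rotate anti-clockwise,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1,0,paper-stated
32,ring bend + wrist rotate clockwise,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,1,paper-stated
33,middle bend + index bend,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,paper-stated
34,middle bend + wrist bend,0,0,1,0,0,0,0,0,0,0,0,0,1,0,0,0,user-supplied
35,thumb down + wrist bend,0,0,0,0,0,0,0,0,1,0,0,0,1,0,0,0,user-supplied
36,thumb up + wrist stretch,0,0,0,0,0,0,0,0,0,1,0,0,0,1,0,0,user-supplied
37,index bend + wrist rotate acw,1,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,user-supplied
38,middle bend + wrist rotate acw,0,0,1,0,0,0,0,0,0,0,0,0,0,0,1,0,user-supplied
39,little bend + wrist rotate acw,0,0,0,0,0,0,1,0,0,0,0,0,0,0,1,0,user-supplied
40,index bend + wrist rotate cw,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,user-supplied
41,middle bend + wrist rotate cw,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,1,user-supplied
42,little bend + wrist rotate cw,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,1,user-supplied
43,wrist bend + rotate acw,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1,0,user-supplied
44,wrist bend + rotate cw,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,1,user-supplied
45,wrist stretch + rotate acw,0,0,0,0,0,0,0,0,0,0,0,0,0,1,1,0,user-supplied
46,wrist stretch + rotate cw,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1,user-supplied
47,thumb + middle pinch,0,0,1,0,0,0,0,0,1,0,0,0,0,0,0,0,user-supplied
48,thumb + ring pinch,0,0,0,0,1,0,0,0,1,0,0,0,0,0,0,0,user-supplied
49,thumb + little pinch,0,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,user-supplied
50,thumb left + wrist rotate acw,0,0,0,0,0,0,0,0,0,0,1,0,0,0,1,0,user-supplied
51,thumb left + wrist rotate cw,0,0,0,0,0,0,0,0,0,0,1,0,0,0,0,1,user-supplied
52,thumb up + index stretch,0,1,0,0,0,0,0,0,0,1,0,0,0,0,0,0,user-supplied
53,index + middle stretch,0,1,0,1,0,0,0,0,0,0,0,0,0,0,0,0,user-supplied
54,middle + ring stretch,0,0,0,1,0,1,0,0,0,0,0,0,0,0,0,0,user-supplied
55,ring + little stretch,0,0,0,0,0,1,0,1,0,0,0,0,0,0,0,0,user-supplied
56,index + middle + ring stretch,0,1,0,1,0,1,0,0,0,0,0,0,0,0,0,0,user-supplied
57,open hand,0,1,0,1,0,1,0,1,0,1,0,0,0,0,0,0,user-supplied
58,D2-D5 extension (1st instance),0,1,0,1,0,1,0,1,0,0,0,0,0,0,0,0,paper-stated
59,open hand + wrist stretch,0,1,0,1,0,1,0,1,0,0,0,0,0,1,0,0,user-supplied
60,D2-D5 extension (2nd instance),0,1,0,1,0,1,0,1,0,0,0,0,0,0,0,0,paper-stated
61,thumb left-down,0,0,0,0,0,0,0,0,1,0,1,0,0,0,0,0,user-supplied
62,thumb right-down,0,0,0,0,0,0,0,0,1,0,0,1,0,0,0,0,user-supplied
63,thumb left-up,0,0,0,0,0,0,0,0,0,1,1,0,0,0,0,0,user-supplied
64,thumb right-up,0,0,0,0,0,0,0,0,0,1,0,1,0,0,0,0,user-supplied
65,four-finger bend + wrist bend,1,0,1,0,1,0,1,0,0,0,0,0,1,0,0,0,user-supplied
66,pinch + wrist rotate acw,1,0,0,0,0,0,0,0,1,0,0,0,0,0,1,0,user-supplied
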