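sample_id,K1,K2,K3,K4,K5,sepal_length,sepal_width,petal_length,petal_width,species
0,1,2,2,1,4,5.1,3.5,1.4,0.2,setosa
1,1,2,2,1,4,4.9,3.0,1.4,0.2,setosa
2,1,2,2,1,4,4.7,3.2,1.3,0.2,setosa
3,1,2,2,1,4,4.6,3.1,1.5,0.2,setosa
4,1,2,2,1,4,5.0,3.6,1.4,0.2,setosa
5,1,2,2,1,4,5.4,3.9,1.7,0.4,setosa
6,1,2,2,1,4,4.6,3.4,1.4,0.3,setosa
7,1,2,2,1,4,5.0,3.4,1.5,0.2,setosa
8,1,2,2,1,4,4.4,2.9,1.4,0.2,setosa
9,1,2,2,1,4,4.9,3.1,1.5,0.1,setosa
10,1,2,2,1,4,5.4,3.7,1.5,0.2,setosa
11,1,2,2,1,4,4.8,3.4,1.6,0.2,setosa
12,1,2,2,1,4,4.8,3.0,1.4,0.1,setosa
13,1,2,2,1,4,4.3,3.0,1.1,0.1,setosa
14,1,2,2,1,4,5.8,4.0,1.2,0.2,setosa
15,1,2,2,1,4,5.7,4.4,1.5,0.4,setosa
16,1,2,2,1,4,5.4,3.9,1.3,0.4,setosa
17,1,2,2,1,4,5.1,3.5,1.4,0.3,setosa
18,1,2,2,1,4,5.7,3.8,1.7,0.3,setosa
19,1,2,2,1,4,5.1,3.8,1.5,0.3,setosa
20,1,2,2,1,4,5.4,3.4,1.7,0.2,setosa
21,1,2,2,1,4,5.1,3.7,1.5,0.4,setosa
22,1,2,2,1,4,4.6,3.6,1.0,0.2,setosa
23,1,2,2,1,4,5.1,3.3,1.7,0.5,setosa
24,1,2,2,1,4,4.8,3.4,1.9,0.2,setosa
25,1,2,2,1,4,5.0,3.0,1.6,0.2,setosa
26,1,2,2,1,4,5.0,3.4,1.6,0.4,setosa
27,1,2,2,1,4,5.2,3.5,1.5,0.2,setosa
28,1,2,2,1,4,5.2,3.4,1.4,0.2,setosa
29,1,2,2,1,4,4.7,3.2,1.6,0.2,setosa
30,1,2,2,1,4,4.8,3.1,1.6,0.2,setosa
31,1,2,2,1,4,5.4,3.4,1.5,0.4,setosa
32,1,2,2,1,4,5.2,4.1,1.5,0.1,setosa
33,1,2,2,1,4,5.5,4.2,1.4,0.2,setosa
34,1,2,2,1,4,4.9,3.1,1.5,0.2,setosa
35,1,2,2,1,4,5.0,3.2,1.2,0.2,setosa
36,1,2,2,1,4,5.5,3.5,1.3,0.2,setosa
37,1,2,2,1,4,4.9,3.6,1.4,0.1,setosa
38,1,2,2,1,4,4.4,3.0,1.3,0.2,setosa
39,1,2,2,1,4,5.1,3.4,1.5,0.2,setosa
40,1,2,2,1,4,5.0,3.5,1.3,0.3,setosa
41,1,2,2,1,4,4.5,2.3,1.3,0.3,setosa
42,1,2,2,1,4,4.4,3.2,1.3,0.2,setosa
43,1,2,2,1,4,5.0,3.5,1.6,0.6,setosa
44,1,2,2,1,4,5.1,3.8,1.9,0.4,setosa
45,1,2,2,1,4,4.8,3.0,1.4,0.3,setosa
46,1,2,2,1,4,5.1,3.8,1.6,0.2,setosa
47,1,2,2,1,4,4.6,3.2,1.4,0.2,setosa
48,1,2,2,1,4,5.3,3.7,1.5,0.2,setosa
49,1,2,2,1,4,5.0,3.3,1.4,0.2,setosa
50,1,1,1,3,1,7.0,3.2,4.7,1.4,versicolor
51,1,1,1,3,1,6.4,3.2,4.5,1.5,versicolor
52,1,1,3,3,1,6.9,3.1,4.9,1.5,versicolor
53,1,1,1,2,2,5.5,2.3,4.0,1.3,versicolor
54,1,1,1,3,1,6.5,2.8,4.6,1.5,versicolor
55,1,1,1,2,2,5.7,2.8,4.5,1.3,versicolor
56,1,1,1,3,1,6.3,3.3,4.7,1.6,versicolor
57,1,2,1,2,2,4.9,2.4,3.3,1.0,versicolor
58,1,1,1,3,1,6.6,2.9,4.6,1.3,versicolor
59,1,1,1,2,2,5.2,2.7,3.9,1.4,versicolor
60,1,1,1,2,2,5.0,2.0,3.5,1.0,versicolor
61,1,1,1,2,2,5.9,3.0,4.2,1.5,versicolor
62,1,1,1,2,2,6.0,2.2,4.0,1.0,versicolor
63,1,1,1,3,1,6.1,2.9,4.7,1.4,versicolor
64,1,1,1,2,2,5.6,2.9,3.6,1.3,versicolor
65,1,1,1,3,1,6.7,3.1,4.4,1.4,versicolor
66,1,1,1,3,2,5.6,3.0,4.5,1.5,versicolor
67,1,1,1,2,2,5.8,2.7,4.1,1.0,versicolor
68,1,1,1,3,1,6.2,2.2,4.5,1.5,versicolor
69,1,1,1,2,2,5.6,2.5,3.9,1.1,versicolor
70,1,1,1,3,1,5.9,3.2,4.8,1.8,versicolor
71,1,1,1,2,2,6.1,2.8,4.0,1.3,versicolor
72,1,1,1,3,1,6.3,2.5,4.9,1.5,versicolor
73,1,1,1,3,1,6.1,2.8,4.7,1.2,versicolor
74,1,1,1,3,1,6.4,2.9,4.3,1.3,versicolor
75,1,1,1,3,1,6.6,3.0,4.4,1.4,versicolor
76,1,1,1,3,1,6.8,2.8,4.8,1.4,versicolor
77,1,1,3,3,1,6.7,3.0,5.0,1.7,versicolor
78,1,1,1,3,1,6.0,2.9,4.5,1.5,versicolor
79,1,1,1,2,2,5.7,2.6,3.5,1.0,versicolor
80,1,1,1,2,2,5.5,2.4,3.8,1.1,versicolor
81,1,1,1,2,2,5.5,2.4,3.7,1.0,versicolor
82,1,1,1,2,2,5.8,2.7,3.9,1.2,versicolor
83,1,1,1,3,1,6.0,2.7,5.1,1.6,versicolor
84,1,1,1,2,2,5.4,3.0,4.5,1.5,versicolor
85,1,1,1,3,1,6.0,3.4,4.5,1.6,versicolor
86,1,1,1,3,1,6.7,3.1,4.7,1.5,versicolor
87,1,1,1,3,1,6.3,2.3,4.4,1.3,versicolor
88,1,1,1,2,2,5.6,3.0,4.1,1.3,versicolor
89,1,1,1,2,2,5.5,2.5,4.0,1.3,versicolor
90,1,1,1,2,2,5.5,2.6,4.4,1.2,versicolor
91,1,1,1,3,1,6.1,3.0,4.6,1.4,versicolor
92,1,1,1,2,2,5.8,2.6,4.0,1.2,versicolor
93,1,2,1,2,2,5.0,2.3,3.3,1.0,versicolor
94,1,1,1,2,2,5.6,2.7,4.2,1.3,versicolor
95,1,1,1,2,2,5.7,3.0,4.2,1.2,versicolor
96,1,1,1,2,2,5.7,2.9,4.2,1.3,versicolor
97,1,1,1,3,1,6.2,2.9,4.3,1.3,versicolor
98,1,2,1,2,2,5.1,2.5,3.0,1.1,versicolor
99,1,1,1,2,2,5.7,2.8,4.1,1.3,versicolor
100,1,1,3,4,5,6.3,3.3,6.0,2.5,virginica
101,1,1,1,3,1,5.8,2.7,5.1,1.9,virginica
102,1,1,3,4,3,7.1,3.0,5.9,2.1,virginica
103,1,1,3,4,5,6.3,2.9,5.6,1.8,virginica
104,1,1,3,4,5,6.5,3.0,5.8,2.2,virginica
105,1,1,3,4,3,7.6,3.0,6.6,2.1,virginica
106,1,1,1,2,2,4.9,2.5,4.5,1.7,virginica
107,1,1,3,4,3,7.3,2.9,6.3,1.8,virginica
108,1,1,3,4,5,6.7,2.5,5.8,1.8,virginica
109,1,1,3,4,3,7.2,3.6,6.1,2.5,virginica
110,1,1,3,3,5,6.5,3.2,5.1,2.0,virginica
111,1,1,3,3,5,6.4,2.7,5.3,1.9,virginica
112,1,1,3,4,5,6.8,3.0,5.5,2.1,virginica
113,1,1,1,3,1,5.7,2.5,5.0,2.0,virginica
114,1,1,1,3,5,5.8,2.8,5.1,2.4,virginica
115,1,1,3,4,5,6.4,3.2,5.3,2.3,virginica
116,1,1,3,4,5,6.5,3.0,5.5,1.8,virginica
117,1,1,3,4,3,7.7,3.8,6.7,2.2,virginica
118,1,1,3,4,3,7.7,2.6,6.9,2.3,virginica
119,1,1,1,3,1,6.0,2.2,5.0,1.5,virginica
120,1,1,3,4,5,6.9,3.2,5.7,2.3,virginica
121,1,1,1,3,1,5.6,2.8,4.9,2.0,virginica
122,1,1,3,4,3,7.7,2.8,6.7,2.0,virginica
123,1,1,1,3,1,6.3,2.7,4.9,1.8,virginica
124,1,1,3,4,5,6.7,3.3,5.7,2.1,virginica
125,1,1,3,4,3,7.2,3.2,6.0,1.8,virginica
126,1,1,1,3,1,6.2,2.8,4.8,1.8,virginica
127,1,1,1,3,1,6.1,3.0,4.9,1.8,virginica
128,1,1,3,4,5,6.4,2.8,5.6,2.1,virginica
129,1,1,3,4,3,7.2,3.0,5.8,1.6,virginica
130,1,1,3,4,3,7.4,2.8,6.1,1.9,virginica
131,1,1,3,4,3,7.9,3.8,6.4,2.0,virginica
132,1,1,3,4,5,6.4,2.8,5.6,2.2,virginica
133,1,1,1,3,1,6.3,2.8,5.1,1.5,virginica
134,1,1,3,3,1,6.1,2.6,5.6,1.4,virginica
135,1,1,3,4,3,7.7,3.0,6.1,2.3,virginica
136,1,1,3,4,5,6.3,3.4,5.6,2.4,virginica
137,1,1,3,4,5,6.4,3.1,5.5,1.8,virginica
138,1,1,1,3,1,6.0,3.0,4.8,1.8,virginica
139,1,1,3,4,5,6.9,3.1,5.4,2.1,virginica
140,1,1,3,4,5,6.7,3.1,5.6,2.4,virginica
141,1,1,3,4,5,6.9,3.1,5.1,2.3,virginica
142,1,1,1,3,1,5.8,2.7,5.1,1.9,virginica
143,1,1,3,4,5,6.8,3.2,5.9,2.3,virginica
144,1,1,3,4,5,6.7,3.3,5.7,2.5,virginica
145,1,1,3,4,5,6.7,3.0,5.2,2.3,virginica
146,1,1,1,3,1,6.3,2.5,5.0,1.9,virginica
147,1,1,3,3,5,6.5,3.0,5.2,2.0,virginica
148,1,1,3,4,5,6.2,3.4,5.4,2.3,virginica
149,1,1,1,3,1,5.9,3.0,5.1,1.8,virginica
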