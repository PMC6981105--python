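subject,scan,days_after_surgery,outcome
1,0,0,0
1,1,111,0
1,2,194,0
2,0,0,0
2,1,11,0
2,2,18,0
2,3,202,0
2,4,286,0
2,5,398,0
3,0,-5,0
3,1,120,0
3,2,204,0
3,3,288,0
3,4,400,0
4,0,-33,0
4,1,1,0
4,2,59,0
4,3,94,0
4,4,225,0
4,5,395,0
5,0,0,1
5,1,190,1
5,2,202,1
5,3,314,1
5,4,488,1
6,0,-11,0
6,1,98,0
6,2,231,0
6,3,413,0
7,0,-31,0
7,1,93,0
7,2,114,0
7,3,116,0
7,4,162,0
8,0,-21,0
8,1,48,0
8,2,100,0
8,3,280,0
8,4,651,0
9,0,-71,0
9,1,147,0
9,2,287,0
9,3,511,0
10,0,-11,0
10,1,390,0
11,0,26,0
11,1,32,0
11,2,138,0
11,3,278,0
11,4,474,0
12,0,0,0
12,1,0,0
12,2,175,0
12,3,287,0
12,4,403,0
13,0,0,0
13,1,2,0
13,2,48,0
14,0,-1,0
14,1,10,0
14,2,143,0
14,3,318,0
14,4,437,0
15,0,-21,0
15,1,25,0
15,2,118,0
15,3,278,0
15,4,481,0
16,0,-24,0
16,1,10,0
16,2,35,0
16,3,51,0
17,0,-4,1
17,1,11,1
17,2,76,1
17,3,260,1
17,4,372,1
18,0,-19,0
18,1,0,0
18,2,0,0
18,3,189,0
18,4,273,0
18,5,357,0
19,0,-12,0
19,1,96,0
19,2,193,0
19,3,216,0
19,4,334,0
20,0,2,0
20,1,81,0
20,2,215,0
20,3,299,0
20,4,355,0
21,0,-2,0
21,1,11,0
21,2,17,0
21,3,201,0
21,4,356,0
22,0,-41,0
22,1,147,0
22,2,343,0
23,0,-13,0
23,1,18,0
23,2,21,0
23,3,165,0
23,4,228,0
24,0,-40,0
24,1,76,0
24,2,163,0
24,3,191,0
24,4,251,0
25,0,-10,0
25,1,55,0
25,2,136,0
25,3,257,0
25,4,440,0
26,0,-40,0
26,1,50,0
26,2,169,0
26,3,309,0
26,4,486,0
27,0,-6,0
27,1,0,0
27,2,89,0
27,3,285,0
28,0,-10,0
28,1,110,0
28,2,446,0
29,0,0,1
29,1,0,1
29,2,124,1
29,3,288,1
29,4,481,1
30,0,-8,1
30,1,12,1
30,2,97,1
30,3,181,1
30,4,321,1
31,0,-2,0
31,1,20,0
31,2,76,0
31,3,84,0
31,4,242,0
31,5,329,0
32,0,-5,0
32,1,20,0
32,2,141,0
32,3,412,0
32,4,612,0
33,0,0,0
33,1,0,0
33,2,108,0
33,3,255,0
33,4,445,0
34,0,-10,1
34,1,4,1
34,2,65,1
34,3,203,1
34,4,297,1
35,0,-10,0
35,1,5,0
35,2,62,0
35,3,165,0
35,4,265,0
36,0,-6,0
36,1,1,0
36,2,93,0
36,3,94,0
36,4,201,0
36,5,322,0
37,0,-2,0
37,1,0,0
37,2,173,0
37,3,509,0
38,0,-10,1
38,1,53,1
38,2,174,1
38,3,218,1
38,4,319,1
39,0,0,1
39,1,0,1
39,2,178,1
39,3,273,1
39,4,424,1
40,0,-10,0
40,1,28,0
40,2,82,0
40,3,166,0
40,4,189,0
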