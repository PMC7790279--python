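patient_id,tech,observer,reading,count
1,dCTA,A,1,0
1,dCTA,A,2,0
1,dCTA,B,1,0
1,dCTA,B,2,0
1,dCTP,A,1,0
1,dCTP,A,2,0
1,dCTP,B,1,0
1,dCTP,B,2,0
1,triphasic,ref,1,0
2,dCTA,A,1,2
2,dCTA,A,2,2
2,dCTA,B,1,2
2,dCTA,B,2,2
2,dCTP,A,1,2
2,dCTP,A,2,2
2,dCTP,B,1,2
2,dCTP,B,2,2
2,triphasic,ref,1,2
3,dCTA,A,1,2
3,dCTA,A,2,2
3,dCTA,B,1,2
3,dCTA,B,2,2
3,dCTP,A,1,2
3,dCTP,A,2,2
3,dCTP,B,1,2
3,dCTP,B,2,2
3,triphasic,ref,1,1
4,dCTA,A,1,0
4,dCTA,A,2,0
4,dCTA,B,1,0
4,dCTA,B,2,0
4,dCTP,A,1,0
4,dCTP,A,2,0
4,dCTP,B,1,0
4,dCTP,B,2,0
4,triphasic,ref,1,0
5,dCTA,A,1,2
5,dCTA,A,2,2
5,dCTA,B,1,2
5,dCTA,B,2,2
5,dCTP,A,1,3
5,dCTP,A,2,3
5,dCTP,B,1,2
5,dCTP,B,2,3
5,triphasic,ref,1,2
6,dCTA,A,1,0
6,dCTA,A,2,0
6,dCTA,B,1,0
6,dCTA,B,2,0
6,dCTP,A,1,0
6,dCTP,A,2,0
6,dCTP,B,1,0
6,dCTP,B,2,0
6,triphasic,ref,1,0
7,dCTA,A,1,1
7,dCTA,A,2,1
7,dCTA,B,1,1
7,dCTA,B,2,1
7,dCTP,A,1,1
7,dCTP,A,2,1
7,dCTP,B,1,1
7,dCTP,B,2,1
7,triphasic,ref,1,1
8,dCTA,A,1,1
8,dCTA,A,2,1
8,dCTA,B,1,1
8,dCTA,B,2,1
8,dCTP,A,1,1
8,dCTP,A,2,1
8,dCTP,B,1,1
8,dCTP,B,2,1
8,triphasic,ref,1,1
9,dCTA,A,1,1
9,dCTA,A,2,1
9,dCTA,B,1,1
9,dCTA,B,2,1
9,dCTP,A,1,1
9,dCTP,A,2,1
9,dCTP,B,1,1
9,dCTP,B,2,1
9,triphasic,ref,1,1
10,dCTA,A,1,0
10,dCTA,A,2,0
10,dCTA,B,1,0
10,dCTA,B,2,0
10,dCTP,A,1,0
10,dCTP,A,2,0
10,dCTP,B,1,0
10,dCTP,B,2,0
10,triphasic,ref,1,0
11,dCTA,A,1,0
11,dCTA,A,2,0
11,dCTA,B,1,0
11,dCTA,B,2,0
11,dCTP,A,1,0
11,dCTP,A,2,0
11,dCTP,B,1,0
11,dCTP,B,2,0
11,triphasic,ref,1,0
12,dCTA,A,1,0
12,dCTA,A,2,0
12,dCTA,B,1,0
12,dCTA,B,2,0
12,dCTP,A,1,0
12,dCTP,A,2,0
12,dCTP,B,1,0
12,dCTP,B,2,0
12,triphasic,ref,1,0
13,dCTA,A,1,0
13,dCTA,A,2,0
13,dCTA,B,1,0
13,dCTA,B,2,0
13,dCTP,A,1,0
13,dCTP,A,2,0
13,dCTP,B,1,0
13,dCTP,B,2,0
13,triphasic,ref,1,0
14,dCTA,A,1,0
14,dCTA,A,2,0
14,dCTA,B,1,0
14,dCTA,B,2,0
14,dCTP,A,1,0
14,dCTP,A,2,0
14,dCTP,B,1,0
14,dCTP,B,2,0
14,triphasic,ref,1,0
15,dCTA,A,1,0
15,dCTA,A,2,0
15,dCTA,B,1,0
15,dCTA,B,2,0
15,dCTP,A,1,0
15,dCTP,A,2,0
15,dCTP,B,1,0
15,dCTP,B,2,0
15,triphasic,ref,1,0
16,dCTA,A,1,0
16,dCTA,A,2,0
16,dCTA,B,1,0
16,dCTA,B,2,0
16,dCTP,A,1,0
16,dCTP,A,2,0
16,dCTP,B,1,0
16,dCTP,B,2,0
16,triphasic,ref,1,0
17,dCTA,A,1,0
17,dCTA,A,2,0
17,dCTA,B,1,0
17,dCTA,B,2,0
17,dCTP,A,1,0
17,dCTP,A,2,0
17,dCTP,B,1,0
17,dCTP,B,2,0
17,triphasic,ref,1,0
18,dCTA,A,1,0
18,dCTA,A,2,0
18,dCTA,B,1,0
18,dCTA,B,2,0
18,dCTP,A,1,0
18,dCTP,A,2,0
18,dCTP,B,1,0
18,dCTP,B,2,0
18,triphasic,ref,1,0
19,dCTA,A,1,1
19,dCTA,A,2,1
19,dCTA,B,1,1
19,dCTA,B,2,1
19,dCTP,A,1,1
19,dCTP,A,2,1
19,dCTP,B,1,1
19,dCTP,B,2,1
19,triphasic,ref,1,1
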