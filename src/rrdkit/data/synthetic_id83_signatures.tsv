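channel	ID1	ID2	ID8
1:Del:C:0	0.0	0.00390625	0.00990099
1:Del:C:1	0.0	0.00390625	0.0
1:Del:C:2	0.0	0.00390625	0.0
1:Del:C:3	0.0	0.00390625	0.0
1:Del:C:4	0.0	0.00390625	0.0
1:Del:C:5	0.0	0.00390625	0.0
1:Del:T:0	0.0	0.00976562	0.00990099
1:Del:T:1	0.0	0.01953125	0.0
1:Del:T:2	0.0	0.04882812	0.0
1:Del:T:3	0.0	0.09765625	0.0
1:Del:T:4	0.0	0.34179687	0.0
1:Del:T:5	0.0	0.45898437	0.0
1:Ins:C:0	0.00485437	0.0	0.0
1:Ins:C:1	0.00485437	0.0	0.0
1:Ins:C:2	0.00485437	0.0	0.0
1:Ins:C:3	0.00485437	0.0	0.0
1:Ins:C:4	0.00485437	0.0	0.0
1:Ins:C:5	0.00485437	0.0	0.0
1:Ins:T:0	0.00970874	0.0	0.0
1:Ins:T:1	0.01941748	0.0	0.0
1:Ins:T:2	0.03883495	0.0	0.0
1:Ins:T:3	0.0776699	0.0	0.0
1:Ins:T:4	0.29126214	0.0	0.0
1:Ins:T:5	0.53398058	0.0	0.0
2:Del:R:0	0.0	0.0	0.07920792
2:Del:R:1	0.0	0.0	0.03960396
2:Del:R:2	0.0	0.0	0.0
2:Del:R:3	0.0	0.0	0.0
2:Del:R:4	0.0	0.0	0.0
2:Del:R:5	0.0	0.0	0.0
3:Del:R:0	0.0	0.0	0.07920792
3:Del:R:1	0.0	0.0	0.03960396
3:Del:R:2	0.0	0.0	0.0
3:Del:R:3	0.0	0.0	0.0
3:Del:R:4	0.0	0.0	0.0
3:Del:R:5	0.0	0.0	0.0
4:Del:R:0	0.0	0.0	0.07920792
4:Del:R:1	0.0	0.0	0.03960396
4:Del:R:2	0.0	0.0	0.0
4:Del:R:3	0.0	0.0	0.0
4:Del:R:4	0.0	0.0	0.0
4:Del:R:5	0.0	0.0	0.0
5:Del:R:0	0.0	0.0	0.07920792
5:Del:R:1	0.0	0.0	0.03960396
5:Del:R:2	0.0	0.0	0.0
5:Del:R:3	0.0	0.0	0.0
5:Del:R:4	0.0	0.0	0.0
5:Del:R:5	0.0	0.0	0.0
2:Ins:R:0	0.0	0.0	0.0
2:Ins:R:1	0.0	0.0	0.0
2:Ins:R:2	0.0	0.0	0.0
2:Ins:R:3	0.0	0.0	0.0
2:Ins:R:4	0.0	0.0	0.0
2:Ins:R:5	0.0	0.0	0.0
3:Ins:R:0	0.0	0.0	0.0
3:Ins:R:1	0.0	0.0	0.0
3:Ins:R:2	0.0	0.0	0.0
3:Ins:R:3	0.0	0.0	0.0
3:Ins:R:4	0.0	0.0	0.0
3:Ins:R:5	0.0	0.0	0.0
4:Ins:R:0	0.0	0.0	0.0
4:Ins:R:1	0.0	0.0	0.0
4:Ins:R:2	0.0	0.0	0.0
4:Ins:R:3	0.0	0.0	0.0
4:Ins:R:4	0.0	0.0	0.0
4:Ins:R:5	0.0	0.0	0.0
5:Ins:R:0	0.0	0.0	0.0
5:Ins:R:1	0.0	0.0	0.0
5:Ins:R:2	0.0	0.0	0.0
5:Ins:R:3	0.0	0.0	0.0
5:Ins:R:4	0.0	0.0	0.0
5:Ins:R:5	0.0	0.0	0.0
2:Del:M:1	0.0	0.0	0.0990099
3:Del:M:1	0.0	0.0	0.07920792
3:Del:M:2	0.0	0.0	0.03960396
4:Del:M:1	0.0	0.0	0.05940594
4:Del:M:2	0.0	0.0	0.03960396
4:Del:M:3	0.0	0.0	0.01980198
5:Del:M:1	0.0	0.0	0.05940594
5:Del:M:2	0.0	0.0	0.03960396
5:Del:M:3	0.0	0.0	0.02970297
5:Del:M:4	0.0	0.0	0.01980198
5:Del:M:5	0.0	0.0	0.01980198
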