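Context	DS	SS
1:Del:C:0	0.0	0.0
1:Del:C:1	0.072	0.03
1:Del:C:2	0.048	0.02
1:Del:C:3	0.015	0.020999999999999998
1:Del:C:4	0.0	0.0
1:Del:C:5	0.0	0.0
1:Del:T:0	0.012	0.005
1:Del:T:1	0.132	0.055
1:Del:T:2	0.108	0.045
1:Del:T:3	0.06	0.025
1:Del:T:4	0.0625	0.0875
1:Del:T:5	0.05	0.06999999999999999
1:Ins:C:0	0.036	0.015
1:Ins:C:1	0.0	0.0
1:Ins:C:2	0.0	0.0
1:Ins:C:3	0.0	0.0
1:Ins:C:4	0.0	0.0
1:Ins:C:5	0.0	0.0
1:Ins:T:0	0.06	0.025
1:Ins:T:1	0.048	0.02
1:Ins:T:2	0.0	0.0
1:Ins:T:3	0.03	0.041999999999999996
1:Ins:T:4	0.02	0.027999999999999997
1:Ins:T:5	0.0	0.0
2:Del:R:0	0.057	0.098
2:Del:R:1	0.039	0.066
2:Del:R:2	0.02	0.027999999999999997
2:Del:R:3	0.0	0.0
2:Del:R:4	0.0	0.0
2:Del:R:5	0.0	0.0
3:Del:R:0	0.024	0.064
3:Del:R:1	0.0	0.0
3:Del:R:2	0.0	0.0
3:Del:R:3	0.0	0.0
3:Del:R:4	0.0	0.0
3:Del:R:5	0.0	0.0
4:Del:R:0	0.018	0.048
4:Del:R:1	0.0	0.0
4:Del:R:2	0.0	0.0
4:Del:R:3	0.0	0.0
4:Del:R:4	0.0	0.0
4:Del:R:5	0.0	0.0
5:Del:R:0	0.0	0.0
5:Del:R:1	0.0	0.0
5:Del:R:2	0.0	0.0
5:Del:R:3	0.0	0.0
5:Del:R:4	0.0	0.0
5:Del:R:5	0.0	0.0
2:Ins:R:0	0.0	0.0
2:Ins:R:1	0.0225	0.0315
2:Ins:R:2	0.0	0.0
2:Ins:R:3	0.0	0.0
2:Ins:R:4	0.0	0.0
2:Ins:R:5	0.0	0.0
3:Ins:R:0	0.0	0.0
3:Ins:R:1	0.0	0.0
3:Ins:R:2	0.0	0.0
3:Ins:R:3	0.0	0.0
3:Ins:R:4	0.0	0.0
3:Ins:R:5	0.0	0.0
4:Ins:R:0	0.0	0.0
4:Ins:R:1	0.0	0.0
4:Ins:R:2	0.0	0.0
4:Ins:R:3	0.0	0.0
4:Ins:R:4	0.0	0.0
4:Ins:R:5	0.0	0.0
5:Ins:R:0	0.0	0.0
5:Ins:R:1	0.0	0.0
5:Ins:R:2	0.0	0.0
5:Ins:R:3	0.0	0.0
5:Ins:R:4	0.0	0.0
5:Ins:R:5	0.0	0.0
2:Del:M:1	0.021	0.05600000000000001
3:Del:M:1	0.015	0.04000000000000001
3:Del:M:2	0.0075	0.020000000000000004
4:Del:M:1	0.0105	0.028000000000000004
4:Del:M:2	0.006	0.016
4:Del:M:3	0.0	0.0
5:Del:M:1	0.006	0.016
5:Del:M:2	0.0	0.0
5:Del:M:3	0.0	0.0
5:Del:M:4	0.0	0.0
5:Del:M:5	0.0	0.0
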