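Context	ID_aging	ID_repeat	ID_deletion
1:Del:C:0	0.0	0.0	0.0
1:Del:C:1	0.12	0.0	0.0
1:Del:C:2	0.08	0.0	0.0
1:Del:C:3	0.0	0.06	0.0
1:Del:C:4	0.0	0.0	0.0
1:Del:C:5	0.0	0.0	0.0
1:Del:T:0	0.02	0.0	0.0
1:Del:T:1	0.22	0.0	0.0
1:Del:T:2	0.18	0.0	0.0
1:Del:T:3	0.1	0.0	0.0
1:Del:T:4	0.0	0.25	0.0
1:Del:T:5	0.0	0.2	0.0
1:Ins:C:0	0.06	0.0	0.0
1:Ins:C:1	0.0	0.0	0.0
1:Ins:C:2	0.0	0.0	0.0
1:Ins:C:3	0.0	0.0	0.0
1:Ins:C:4	0.0	0.0	0.0
1:Ins:C:5	0.0	0.0	0.0
1:Ins:T:0	0.1	0.0	0.0
1:Ins:T:1	0.08	0.0	0.0
1:Ins:T:2	0.0	0.0	0.0
1:Ins:T:3	0.0	0.12	0.0
1:Ins:T:4	0.0	0.08	0.0
1:Ins:T:5	0.0	0.0	0.0
2:Del:R:0	0.04	0.0	0.22
2:Del:R:1	0.0	0.12	0.06
2:Del:R:2	0.0	0.08	0.0
2:Del:R:3	0.0	0.0	0.0
2:Del:R:4	0.0	0.0	0.0
2:Del:R:5	0.0	0.0	0.0
3:Del:R:0	0.0	0.0	0.16
3:Del:R:1	0.0	0.0	0.0
3:Del:R:2	0.0	0.0	0.0
3:Del:R:3	0.0	0.0	0.0
3:Del:R:4	0.0	0.0	0.0
3:Del:R:5	0.0	0.0	0.0
4:Del:R:0	0.0	0.0	0.12
4:Del:R:1	0.0	0.0	0.0
4:Del:R:2	0.0	0.0	0.0
4:Del:R:3	0.0	0.0	0.0
4:Del:R:4	0.0	0.0	0.0
4:Del:R:5	0.0	0.0	0.0
5:Del:R:0	0.0	0.0	0.0
5:Del:R:1	0.0	0.0	0.0
5:Del:R:2	0.0	0.0	0.0
5:Del:R:3	0.0	0.0	0.0
5:Del:R:4	0.0	0.0	0.0
5:Del:R:5	0.0	0.0	0.0
2:Ins:R:0	0.0	0.0	0.0
2:Ins:R:1	0.0	0.09	0.0
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
2:Del:M:1	0.0	0.0	0.14
3:Del:M:1	0.0	0.0	0.1
3:Del:M:2	0.0	0.0	0.05
4:Del:M:1	0.0	0.0	0.07
4:Del:M:2	0.0	0.0	0.04
4:Del:M:3	0.0	0.0	0.0
5:Del:M:1	0.0	0.0	0.04
5:Del:M:2	0.0	0.0	0.0
5:Del:M:3	0.0	0.0	0.0
5:Del:M:4	0.0	0.0	0.0
5:Del:M:5	0.0	0.0	0.0
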