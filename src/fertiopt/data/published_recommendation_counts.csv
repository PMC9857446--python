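age_group,expose_all_n,fewer_n
<32,19373,77761
32-34,27834,61248
35-37,45346,42260
38-40,59223,14211
41-42,35819,724
>42,26856,64
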