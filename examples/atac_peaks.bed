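chr3	23009800	23011300	peak_1
chr3	23020000	23020600	peak_2
chr3	23040100	23040900	peak_3
chr3	23047000	23047500	peak_4
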