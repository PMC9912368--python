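top_level_digit	ethnicity4
1	White
2	Other
3	Asian
4	Black
5	Other
6	Other
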