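chromosome	total_length	gap_length	effective_length	gap_count
Chr1	507515187	188860	507326327	39
Chr2	654279071	57881	654221190	36
Chr3	629928798	213896	629714902	63
Chr4	528822301	104851	528717450	48
Chr5	584392136	236951	584155185	51
Chr6	497522035	233166	497288869	38
Chr7	652241641	335886	651905755	76
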