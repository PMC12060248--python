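chromosome	total_length	gap_length	effective_length	gap_count
Chr1	501967303	8406331	493560972	6647
Chr2	650458083	8558830	641899253	8139
Chr3	627456150	9202775	618253375	9437
Chr4	525206139	8086205	517119934	6175
Chr5	576238907	12629354	563609553	7615
Chr6	495363004	7581178	487781826	6199
Chr7	644841383	14867162	629974221	8698
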