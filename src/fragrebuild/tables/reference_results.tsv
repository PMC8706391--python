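# reference semi-exhaustive results per group: group, n_kl, bbe_kl, n_sl, n_nl, bbe_nl
1	5	-8.7	25	581	-12.2
2	10	-10.6	48	2061	-12.8
3	15	-11.3	81	5848	-12.4
4	20	-11.0	95	7861	-13.0
5	25	-11.0	114	12266	-12.6
6	30	-11.3	153	10163	-12.9
7	35	-11.3	177	28910	-13.0
8	40	-11.3	237	51514	-11.4
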