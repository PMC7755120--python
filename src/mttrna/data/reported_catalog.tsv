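position	reported
4373	N
4452	Y
5558	Y
5587	Y
5595	N
5774	Y
5794	N
5819	N
7502	Y
10055	N
12141	N
12279	N
14692	N
15910	N
15948	N
15950	N
15952	N
15992	N
593	Y
636	N
1607	N
1664	Y
3290	Y
4363	Y
4369	N
4385	N
4386	Y
4394	Y
5567	Y
5601	Y
5628	Y
5773	Y
5783	Y
5786	Y
5814	Y
5821	Y
5823	Y
5836	Y
5843	Y
5878	N
7492	Y
7572	N
8343	Y
9992	N
10007	Y
10031	Y
10410	Y
10411	Y
10454	Y
10463	Y
12153	Y
12172	Y
12190	N
12192	N
12216	N
12231	N
12280	Y
14687	Y
14693	Y
14696	Y
14727	Y
15889	Y
15900	Y
15924	Y
15927	Y
15928	Y
15930	Y
15932	Y
15937	Y
15940	Y
15951	Y
15968	Y
16000	Y
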