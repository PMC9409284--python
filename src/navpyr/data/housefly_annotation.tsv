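domain	segment	first	last	anchor
1	k	243	254	243
1	o	255	281	255
1	i	392	434	392
1	i	435	446	391
2	k	908	919	908
2	o	920	947	920
2	p	960	982	936
2	p	983	995	935
2	i	999	1030	999
3	k	1401	1412	1401
3	p	1480	1500	1448
3	i	1522	1555	1522
4	i	1821	1850	1821
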