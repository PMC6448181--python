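hundred	2
thousand	3
million	6
billion	9
trillion	12
quadrillion	15
quintillion	18
sextillion	21
septillion	24
octillion	27
nonillion	30
decillion	33
undecillion	36
googol	100
googolplex	non_representable
infinity	infinite
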