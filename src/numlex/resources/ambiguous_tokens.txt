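i
v
x
iv
va
ic
id
if
1g
3d
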