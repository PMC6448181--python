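quinquagenarian	50	59
sexagenarian	60	69
septuagenarian	70	79
octogenarian	80	89
nonagenarian	90	99
centenarian	100	inf
supercentenarian	110	inf
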