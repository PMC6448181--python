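couple of
lots of
not much
few of
small number of
hundreds of
all kinds of
thousands of
tons of
too many to count
massive amounts of
very small number of
far more than
way more than
very large number of
millions of
way too many
huge number of
gobs of
vanishingly small
uncountable
hell of a lot
lion's share of
vast quantities of
waist deep in
infinitesimally small
tiny number of
infinitely more
miniscule amounts of
gazillion
crap load of
shit load
up the wazoo
infinitely small
bazillion
infinitely less
infinitely large
butt load
boat loads of
buttload
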