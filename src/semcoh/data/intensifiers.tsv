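# word	multiplier — applied to the polarity of the immediately following
# lexicon match; >1 amplifies, <1 attenuates.  Single tokens only; negation
# cues live in negators.txt and take precedence.
very	1.3
really	1.25
extremely	1.5
incredibly	1.6
unbelievably	1.6
insanely	1.6
absolutely	1.5
completely	1.4
totally	1.4
utterly	1.5
deeply	1.3
highly	1.3
especially	1.25
particularly	1.25
so	1.2
too	1.2
super	1.35
truly	1.3
quite	1.1
pretty	1.1
fairly	0.9
rather	0.95
somewhat	0.8
slightly	0.7
mildly	0.75
kinda	0.8
sorta	0.8
marginally	0.7
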