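# Negation cues: a lexicon match preceded by one of these within the
# negation window has its polarity sign-flipped and damped.
not
no
never
none
nobody
nothing
neither
nor
cannot
can't
cant
don't
dont
doesn't
doesnt
didn't
didnt
won't
wont
wouldn't
wouldnt
shouldn't
shouldnt
couldn't
couldnt
isn't
isnt
aren't
arent
wasn't
wasnt
weren't
werent
haven't
havent
hasn't
hasnt
hadn't
hadnt
ain't
aint
without
hardly
scarcely
barely
seldom
rarely
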