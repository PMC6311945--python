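# Default trigger lexicon: <term>[\t<category>], matched case-insensitively
# with inflection folding (associate/associated/association are one family).
associated	verb
association	noun
cause	verb
caused	verb
causes	verb
linked	verb
correlated	verb
related	verb
results in	verb
responsible for	preposition
risk	noun
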