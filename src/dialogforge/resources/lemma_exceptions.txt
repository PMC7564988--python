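# Irregular or rule-resistant lemma mappings: "surface lemma" per line.
# Regular plurals and superlatives are handled by suffix rules; unknown
# words pass through unchanged.
closest close
closer close
best good
better good
worst bad
worse bad
children child
teeth tooth
feet foot
men man
women woman
mice mouse
made make
gone go
went go
has have
had have
was be
were be
is be
are be
been be
being be
dentures denture
nappies nappy
braces brace
dishes dish
brushes brush
glasses glass
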