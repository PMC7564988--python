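# Past-participle inventory for the template-based passive transformation.
# The passive rule only fires for verbs listed here; multi-word verb heads
# (help to use, ...) are intentionally absent and are skipped with a warning.
add: added
set: set
put: put
clean: cleaned
wash: washed
brush: brushed
scrub: scrubbed
wipe: wiped
sponge: sponged
prepare: prepared
make: made
cook: cooked
fix: fixed
change: changed
swap: swapped
replace: replaced
exchange: exchanged
record: recorded
rinse: rinsed
polish: polished
attaching: attached
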