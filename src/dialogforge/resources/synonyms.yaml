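# Static keyword-synonym lexicon for the paraphrase synonym rule.
# Stands in front of embedding-derived synonym lookup so that generation is
# fully offline; entries follow the action-verb inventory of the fixture
# ontology plus the documented replacement families (clean -> wash/scrub/
# wipe/sponge, add -> attaching/put/set).
clean: [wash, scrub, wipe, sponge]
add: [attaching, put, set]
wash: [clean, rinse, scrub]
brush: [scrub, polish]
set: [put, record, add]
put: [set, record]
prepare: [make, cook, fix]
make: [prepare, cook]
cook: [prepare, make]
change: [swap, replace, exchange]
help to use: [assist to use]
assist to use: [help to use]
help to: [assist to]
assist to: [help to]
help to change: [assist to change]
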