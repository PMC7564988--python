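# Contraction expansion table applied before tokenization (case-insensitive).
"i'm": i am
"i've": i have
"i'll": i will
"i'd": i would
"you're": you are
"you've": you have
"you'll": you will
"he's": he is
"she's": she is
"it's": it is
"we're": we are
"we've": we have
"they're": they are
"they've": they have
"isn't": is not
"aren't": are not
"wasn't": was not
"weren't": were not
"don't": do not
"doesn't": does not
"didn't": did not
"can't": cannot
"couldn't": could not
"won't": will not
"wouldn't": would not
"shouldn't": should not
"haven't": have not
"hasn't": has not
"hadn't": had not
"let's": let us
"that's": that is
"there's": there is
"what's": what is
"who's": who is
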