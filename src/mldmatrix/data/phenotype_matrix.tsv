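severity	severe	moderate	mild	benign	unknown
severe	infantile	juvenile	adult	asymptomatic	unknown
moderate	juvenile	adult	asymptomatic	asymptomatic	unknown
mild	adult	asymptomatic	asymptomatic	asymptomatic	unknown
benign	asymptomatic	asymptomatic	asymptomatic	asymptomatic	asymptomatic
unknown	unknown	unknown	unknown	asymptomatic	unknown
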