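>mellitin honeybee membrane-active toxin, 26 aa
GIGAVLKVLTTGLPALISWIKRKRQQ
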