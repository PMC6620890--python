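no
nada
nadie
nunca
jamás
ni
ningún
ninguno
ninguna
tampoco
sin
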