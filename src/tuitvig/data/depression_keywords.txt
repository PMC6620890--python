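agobiado/a
agotado/a
angustiado/a
ansiedad
ansioso/a
cansado/a
decaído
depresión
depresivo/a
deprimido/a
desanimado/a
desesperado/a
desmotivado/a
insomnio
llorar
nervioso
preocupado/a
solo/a
triste
vacío/a
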