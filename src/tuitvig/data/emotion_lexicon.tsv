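abatida	sadness
abatido	sadness
aborrecer	disgust
agridulce	happiness
agridulce	sadness
alegre	happiness
alegres	happiness
alegría	happiness
angustia	fear
angustia	sadness
apenada	sadness
apenado	sadness
asco	disgust
asombrada	surprise
asombrado	surprise
asombro	surprise
asqueada	disgust
asqueado	disgust
asquerosa	disgust
asqueroso	disgust
asustada	fear
asustado	fear
aterrada	fear
aterrado	fear
atónita	surprise
atónito	surprise
cabreada	anger
cabreado	anger
contenta	happiness
contentas	happiness
contento	happiness
contentos	happiness
deprimida	sadness
deprimido	sadness
desconsolada	sadness
desconsolado	sadness
dichosa	happiness
dichoso	happiness
encantada	happiness
encantado	happiness
enfadada	anger
enfadado	anger
enojo	anger
espanto	fear
euforia	happiness
felices	happiness
felicidad	happiness
feliz	happiness
furia	anger
furiosa	anger
furioso	anger
gozo	happiness
ilusionada	happiness
ilusionado	happiness
impactada	surprise
impactado	surprise
indignada	anger
indignado	anger
inesperada	surprise
inesperado	surprise
ira	anger
irritada	anger
irritado	anger
júbilo	happiness
luto	sadness
lágrima	sadness
lágrimas	sadness
melancolía	sadness
miedo	fear
náusea	disgust
odiar	anger
odio	anger
pena	sadness
pánico	fear
rabia	anger
rencor	anger
repugnancia	disgust
repugnante	disgust
repugnantes	disgust
repulsión	disgust
reír	happiness
risueña	happiness
risueño	happiness
sollozar	sadness
sonreír	happiness
sorprendida	surprise
sorprendido	surprise
sorpresa	surprise
susto	fear
temer	fear
temerosa	fear
temeroso	fear
temor	fear
terror	fear
triste	sadness
tristes	sadness
tristeza	sadness
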