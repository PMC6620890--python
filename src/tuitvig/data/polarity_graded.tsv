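aberrante	-0.80
aberrantes	-0.80
abominable	-0.80
abominables	-0.80
aburrida	-0.40
aburridas	-0.40
aburrido	-0.40
aburridos	-0.40
aceptable	+0.40
aceptables	+0.40
agradable	+0.40
agradables	+0.40
atroz	-0.80
atrozes	-0.80
catastrófica	-0.80
catastróficas	-0.80
catastrófico	-0.80
catastróficos	-0.80
correcta	+0.40
correctas	+0.40
correcto	+0.40
correctos	+0.40
decente	+0.40
decentes	+0.40
entretenida	+0.40
entretenidas	+0.40
entretenido	+0.40
entretenidos	+0.40
espantosa	-0.80
espantosas	-0.80
espantoso	-0.80
espantosos	-0.80
extraordinaria	+0.80
extraordinarias	+0.80
extraordinario	+0.80
extraordinarios	+0.80
fantástica	+0.80
fantásticas	+0.80
fantástico	+0.80
fantásticos	+0.80
floja	-0.40
flojas	-0.40
flojo	-0.40
flojos	-0.40
gloriosa	+0.80
gloriosas	+0.80
glorioso	+0.80
gloriosos	+0.80
horrenda	-0.80
horrendas	-0.80
horrendo	-0.80
horrendos	-0.80
insulsa	-0.40
insulsas	-0.40
insulso	-0.40
insulsos	-0.40
insuperable	+0.80
insuperables	+0.80
interesante	+0.40
interesantes	+0.40
magnífica	+0.80
magníficas	+0.80
magnífico	+0.80
magníficos	+0.80
majestuosa	+0.80
majestuosas	+0.80
majestuoso	+0.80
majestuosos	+0.80
mediocre	-0.40
mediocres	-0.40
molesta	-0.40
molestas	-0.40
molesto	-0.40
molestos	-0.40
pavorosa	-0.80
pavorosas	-0.80
pavoroso	-0.80
pavorosos	-0.80
razonable	+0.40
razonables	+0.40
sosa	-0.40
sosas	-0.40
soso	-0.40
sosos	-0.40
sublime	+0.80
sublimes	+0.80
torpe	-0.40
torpes	-0.40
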