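admirable	+1
admirables	+1
afortunada	+1
afortunadas	+1
afortunado	+1
afortunados	+1
amable	+1
amables	+1
amarga	-1
amargas	-1
amargo	-1
amargos	-1
amorosa	+1
amorosas	+1
amoroso	+1
amorosos	+1
bonita	+1
bonitas	+1
bonito	+1
bonitos	+1
brillante	+1
brillantes	+1
buena	+1
buenas	+1
bueno	+1
buenos	+1
cariñosa	+1
cariñosas	+1
cariñoso	+1
cariñosos	+1
cruel	-1
crueles	-1
dañina	-1
dañinas	-1
dañino	-1
dañinos	-1
deplorable	-1
deplorables	-1
desastrosa	-1
desastrosas	-1
desastroso	-1
desastrosos	-1
divertida	+1
divertidas	+1
divertido	+1
divertidos	+1
espléndida	+1
espléndidas	+1
espléndido	+1
espléndidos	+1
estupenda	+1
estupendas	+1
estupendo	+1
estupendos	+1
excelente	+1
excelentes	+1
exitosa	+1
exitosas	+1
exitoso	+1
exitosos	+1
fabulosa	+1
fabulosas	+1
fabuloso	+1
fabulosos	+1
fea	-1
feas	-1
feo	-1
feos	-1
formidable	+1
formidables	+1
funesta	-1
funestas	-1
funesto	-1
funestos	-1
generosa	+1
generosas	+1
generoso	+1
generosos	+1
genial	+1
geniales	+1
honesta	+1
honestas	+1
honesto	+1
honestos	+1
horrible	-1
horribles	-1
infame	-1
infames	-1
lamentable	-1
lamentables	-1
limpia	+1
limpias	+1
limpio	+1
limpios	+1
luminosa	+1
luminosas	+1
luminoso	+1
luminosos	+1
mala	-1
malas	-1
malo	-1
malos	-1
maravillosa	+1
maravillosas	+1
maravilloso	+1
maravillosos	+1
miserable	-1
miserables	-1
nefasta	-1
nefastas	-1
nefasto	-1
nefastos	-1
odiosa	-1
odiosas	-1
odioso	-1
odiosos	-1
penosa	-1
penosas	-1
penoso	-1
penosos	-1
perfecta	+1
perfectas	+1
perfecto	+1
perfectos	+1
preciosa	+1
preciosas	+1
precioso	+1
preciosos	+1
pésima	-1
pésimas	-1
pésimo	-1
pésimos	-1
radiante	+1
radiantes	+1
ruin	-1
ruines	-1
sana	+1
sanas	+1
sano	+1
sanos	+1
sucia	-1
sucias	-1
sucio	-1
sucios	-1
tóxica	-1
tóxicas	-1
tóxico	-1
tóxicos	-1
vil	-1
viles	-1
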