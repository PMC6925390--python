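de
la
que
el
en
y
a
los
del
se
las
por
un
para
con
no
una
su
al
lo
como
más
pero
sus
le
ya
o
este
sí
porque
esta
entre
cuando
muy
sin
sobre
también
me
hasta
hay
donde
quien
desde
todo
nos
durante
todos
uno
les
ni
contra
otros
ese
eso
ante
ellos
e
esto
mí
antes
algunos
qué
unos
yo
otro
otras
otra
él
tanto
esa
estos
mucho
quienes
nada
muchos
cual
poco
ella
estar
estas
algunas
algo
nosotros
mi
mis
tú
te
ti
tu
tus
ellas
nosotras
vosotros
vosotras
os
mío
mía
míos
mías
tuyo
tuya
tuyos
tuyas
suyo
suya
suyos
suyas
nuestro
nuestra
nuestros
nuestras
vuestro
vuestra
vuestros
vuestras
esos
esas
estoy
estás
está
estamos
estáis
están
esté
estés
estemos
estéis
estén
estaba
estabas
estábamos
estaban
estuve
estuvo
estuvimos
estuvieron
ser
es
somos
son
sea
seas
seamos
sean
era
eras
éramos
eran
fui
fue
fuimos
fueron
tengo
tienes
tiene
tenemos
tienen
tenga
tengas
tengamos
tengan
tenía
tenías
teníamos
tenían
tuve
tuvo
tuvimos
tuvieron
he
has
ha
hemos
han
haya
hayas
hayamos
hayan
había
habías
habíamos
habían
hube
hubo
hubimos
hubieron
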