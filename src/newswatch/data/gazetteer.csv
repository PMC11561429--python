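code,name,aliases
AR,Argentina,
AU,Australia,
AT,Austria,
BD,Bangladesh,
BE,Belgium,
BO,Bolivia,
BR,Brazil,
CA,Canada,
CL,Chile,
CN,China,People's Republic of China
CO,Colombia,
CU,Cuba,
CZ,Czechia,Czech Republic
DK,Denmark,
EC,Ecuador,
EG,Egypt,
ET,Ethiopia,
FI,Finland,
FR,France,
DE,Germany,
GH,Ghana,
GR,Greece,
HU,Hungary,
IN,India,
ID,Indonesia,
IR,Iran,
IQ,Iraq,
IE,Ireland,
IL,Israel,
IT,Italy,
JP,Japan,
JO,Jordan,
KE,Kenya,
KR,South Korea,Republic of Korea|Korea
MY,Malaysia,
MX,Mexico,
MA,Morocco,
NP,Nepal,
NL,Netherlands,Holland
NZ,New Zealand,
NG,Nigeria,
NO,Norway,
PK,Pakistan,
PE,Peru,
PH,Philippines,
PL,Poland,
PT,Portugal,
RO,Romania,
RU,Russia,Russian Federation
SA,Saudi Arabia,
SN,Senegal,
SG,Singapore,
ZA,South Africa,
ES,Spain,
LK,Sri Lanka,
SE,Sweden,
CH,Switzerland,
TH,Thailand,
TR,Turkey,Turkiye
UG,Uganda,
UA,Ukraine,
AE,United Arab Emirates,UAE
GB,United Kingdom,Britain|Great Britain
US,United States,United States of America|USA|America
UY,Uruguay,
VE,Venezuela,
VN,Vietnam,
ZM,Zambia,
ZW,Zimbabwe,
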