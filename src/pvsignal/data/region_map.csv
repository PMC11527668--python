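country,region
US,North America
USA,North America
UNITED STATES,North America
CA,North America
CANADA,North America
MX,North America
MEXICO,North America
PR,North America
GB,Europe
UNITED KINGDOM,Europe
DE,Europe
GERMANY,Europe
FR,Europe
FRANCE,Europe
IT,Europe
ITALY,Europe
ES,Europe
SPAIN,Europe
NL,Europe
PL,Europe
SE,Europe
CH,Europe
AT,Europe
BE,Europe
DK,Europe
NO,Europe
FI,Europe
IE,Europe
PT,Europe
GR,Europe
CZ,Europe
HU,Europe
RU,Europe
JP,Asia
JAPAN,Asia
CN,Asia
CHINA,Asia
KR,Asia
IN,Asia
TW,Asia
HK,Asia
SG,Asia
TH,Asia
MY,Asia
PH,Asia
VN,Asia
ID,Asia
IL,Asia
SA,Asia
TR,Asia
BR,South America
BRAZIL,South America
AR,South America
CO,South America
CL,South America
PE,South America
VE,South America
EC,South America
UY,South America
ZA,Africa
NG,Africa
EG,Africa
KE,Africa
MA,Africa
TN,Africa
GH,Africa
AU,Oceania
AUSTRALIA,Oceania
NZ,Oceania
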