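country_code,name,income_group,keyword_insomnia,keyword_suicide
AU,Australia,high,Insomnia,Suicide
AT,Austria,high,Schlaflosigkeit,Selbstmord
BO,Bolivia,high,Insomnio,Suicidio
CA,Canada,high,Insomnia,Suicide
CL,Chile,high,Insomnio,Suicidio
CZ,Czech Republic,high,Nespavost,Sebevražda
FI,Finland,high,Unettomuus,Itsemurha
FR,France,high,Insomnie,Suicide
DE,Germany,high,Schlaflosigkeit,Selbstmord
GR,Greece,high,αυπνία,αυτοκτονία
HK,Hong Kong,high,失眠,自殺
HU,Hungary,high,inszomnia,öngyilkosság
IL,Israel,high,נדודי שינה,התאבדות
IT,Italy,high,Insonnia,Suicidio
JP,Japan,high,不眠症,自殺
NL,The Netherlands,high,Slapeloosheid,Zelfmoord
NZ,New Zealand,high,Insomnia,Mate whakamomori
NO,Norway,high,Søvnløs,Selvmord
PL,Poland,high,Bezsenność,Samobójstwo
PT,Portugal,high,Insônia,Suicídio
QA,Qatar,high,الأرق,انتحار
SA,Saudi Arabia,high,الأرق,انتحار
SG,Singapore,high,Insomnia,Suicide
KR,South Korea,high,불면증,자살
ES,Spain,high,Insomnio,Suicidio
SE,Sweden,high,Sömnlös,Självmord
CH,Switzerland,high,Schlafstörung,Selbstmord
TW,Taiwan,high,失眠,自殺
AE,United Arab Emirates,high,الأرق,انتحار
GB,United Kingdom,high,Insomnia,Suicide
US,United States,high,Insomnia,Suicide
AR,Argentina,middle,Insomnio,Suicidio
BR,Brazil,middle,Insônia,Suicídio
CO,Colombia,middle,Insomnio,Suicidio
EG,Egypt,middle,الأرق,انتحار
IN,India,middle,अनिद्रा,आत्महत्या
ID,Indonesia,middle,Insomnia,Bunuh diri
MY,Malaysia,middle,Insomnia,Membunuh diri
MX,Mexico,middle,Insomnio,Suicidio
PE,Peru,middle,Insomnio,Suicidio
ZA,South Africa,middle,Insomnia,Suicide
TH,Thailand,middle,นอนไม่หลับ,ฆ่าตัวตาย
TR,Turkey,middle,Uykusuzluk,Intihar
VE,Venezuela,middle,Insomnio,Suicidio
VN,Vietnam,middle,mất ngủ,tự tử
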