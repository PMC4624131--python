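>Pam18_66-83
VITGFGAFLTLYFTAGAY
>Pam18_120-137
TENTLTKKKLKEVHRKIM
>Pam18_151-168
ATKINEAKDFLEKRGISK
>Pam16_5-22
AFIQVIITGTQVFGKAFA
>Pam16_92-109
GGSFYLQSKVYRAAERLK
>Pam16_107-124
RLKWELAQREKNAKAKAG
>Pam17_4-21
PSVTAAALRSTATTLPLR
>Pam17_52-69
VGSSLFTALLGCNVSWAY
>Pam17_87-104
LTVISAGIIASGALGYLL
>Pam17_112-129
VFKLSHNQQLAQFNNKNK
>Pam17_163-180
KEYKQWLRDCHAYAKKAK
>Tim44_83-100
GESEAYKKAREAYLKAQR
>Tim44_94-110
AYLKAQRGSTIVGKTLKK
>Tim44_126-143
SELGKNTRKAAAATAKKL
>Tim44_180-197
RRLKRERDLASGKRHRAV
>Tim44_217-235
SFGKKVEDFKEKTVVGRS
>Tim44_226-243
KEKTVVGRSIQSLKNKLW
>Tim44_301-318
ILEAYVKGDVKVLKKWFS
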