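position_cm1,assignment,component
1022,CH2OH group vibrations,glycogen
1044,C-O stretching coupled with C-O bending of C-OH groups,glycogen
1050,C-O and C-O-C stretching of carbohydrate moieties,collagen
1064,C-O and C-O-C stretching of carbohydrate moieties,collagen
1080,C-C stretch,glycogen
1084,C-O and C-O-C stretching of carbohydrate moieties,collagen
1155,C-O stretching vibration,glycogen
1164,C-O stretching,collagen
1174,C-O stretching,collagen
1202,amide III,collagen
1230,amide III,collagen
1234,amide III,collagen
1244,amide III,collagen
1250,amide III,collagen
1278,amide III,collagen
1284,amide III,collagen
1304,amide III,collagen
1308,amide III,collagen
1340,CH2 of collagen,collagen
1344,CH2 of collagen,collagen
1404,CH3 of collagen,collagen
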