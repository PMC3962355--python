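>nve-miR-100 synthetic stand-in (1-2 substitutions from the S. pistillata mature)
acccguagauccgaacuuguga
>nve-miR-2022 synthetic stand-in
uuuacuaguugcuuuugucccguu
>hma-miR-2022 synthetic stand-in
uuugcuaguugcuuucgucccgug
>nve-miR-2023 synthetic stand-in
aaagaaguacaaguggucggg
>nve-miR-2030 synthetic stand-in
uagcauaacauuguaagagauu
>nve-miR-2036 synthetic stand-in
uauauuguacgacucucaucgugg
>nve-miR-9001 synthetic unrelated decoy
ugcaucgaucgauggcaucgaa
>nve-miR-9002 synthetic unrelated decoy
ccgaugcuuagcaugcaaucgu
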