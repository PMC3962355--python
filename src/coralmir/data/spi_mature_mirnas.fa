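>spi-miR-temp-1 conserved: miR-100 family
acccguagauccgaacuugugg
>spi-miR-temp-2
uaucgaauccgucaaaaagaga
>spi-miR-temp-3
ucagggauuguggugaguuaguu
>spi-miR-temp-4 conserved: nve-miR-2023
aaagaaguacaagugguaggg
>spi-miR-temp-5
gagguccggaugguuga
>spi-miR-temp-6
uaucgauuccgucaaaaagaga
>spi-miR-temp-7
uaugauaucguauccuuugagg
>spi-miR-temp-8
aaguuugagauuugauuuacugaag
>spi-miR-temp-9
ucucugaaaucuccuaagcuauca
>spi-miR-temp-10
ucaguuccaccaucucaccuaua
>spi-miR-temp-12
ggaguuuguuguacugugcuauu
>spi-miR-temp-13
ugggauuaaaacuucuucggugugg
>spi-miR-temp-14
caauguuucggcuuguucccg
>spi-miR-temp-15
ucaagucuaggcugguuaguuu
>spi-miR-temp-16
uuuaguuuuccgauauuuuuagg
>spi-miR-temp-17
ugaacccagaaccucgaagg
>spi-miR-temp-18
ugaaauacucugacggagucagu
>spi-miR-temp-19
ugucauauccauccaaacgagg
>spi-miR-temp-20
ugugauuggagacuuuuaucgu
>spi-miR-temp-22
ccgauuugaacaauguuccguuc
>spi-miR-temp-23
aaauugcuccgaaauacaucuau
>spi-miR-temp-25 conserved: nve-miR-2022 and hma-miR-2022
uuugcuaguugcuuuugucccguu
>spi-miR-temp-26
uccagcaccaauguuauuguua
>spi-miR-temp-29
uggcauaagggcagccaccccuu
>spi-miR-temp-30 conserved: nve-miR-2036
uauauuguacgacucucaucgugu
>spi-miR-temp-33
ccaacugugacugcaaauuaau
>spi-miR-temp-34
acugauauucaccaagugauua
>spi-miR-temp-36
gaaaaguucgucgaucacucg
>spi-miR-temp-38
ucaguuccaccaucucaccuac
>spi-miR-temp-40 conserved: nve-miR-2030
uagcauaacauuguaagagauc
>spi-miR-temp-42
ugugcaagaauuugagucgcugg
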