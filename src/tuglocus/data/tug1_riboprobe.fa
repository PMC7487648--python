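>Tug1_riboprobe_492nt mouse Tug1 in situ hybridization riboprobe (RNA, as published)
GAGACACGACUCACCAAGCACUGCCACCAGCACUGUCACUGGGAACUUGAAGAUCCAAGUUUCUGUCCAG
AACCUCAGUGCAAACUGACAACACUCCAUCCAAAGUGAACUACGUCCCGUGCCUCCUGAUUGCUGAAUGU
UCACCUGGACCUGCCAAUGACCUUCCUUCUGCUACUCCAUCAGCCUACAGACCUGGUACUUGGAUUUUUG
UCCAUGGUGAUUCCUUCCACCUUACUACUGAAGAAGACACCAUUCCAGUGGACCACUGUGACCCAAGAAG
CAUUCAGCCAUCAUGAUGUGGCCUUUACCUCCACUCCUGUCCUACUCUGCCCAGAUUCAGCACAGCCCUU
UAUAGUGCAGUCAAGAGUCUUCAAGCCAAAUAACUGAAGCUAUUUUAUCACAACAAAGGCCAGGUUUAUU
CCAUAAAUGUACAGUUCAUUUCUGCAGUUUAUUCUUCAGAGACACAUAGUAAAUUUGGACCAGGGGAUUU
UG
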