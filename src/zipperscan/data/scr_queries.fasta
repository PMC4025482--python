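>Scr_plus SCR N-terminus, wild type
FAMSSYQFVNSLACYPQMN
>Scr14 SCR N-terminus, Ser10->Leu
FAMSLYQFVNSLACYPQMN
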