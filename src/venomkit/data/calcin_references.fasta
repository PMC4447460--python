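>P59868 Imperatoxin-A (Pandinus imperator) ryanodine-receptor calcin, 33 aa; transcribed reference sequence
GDCLPHLKRCKADNDCCGKKCKRRGTNAEKRCR
>P60254 Maurocalcin (Scorpio maurus palmatus) ryanodine-receptor calcin, 33 aa; transcribed reference sequence
GDCLPHLKLCKENKDCCSKKCKRRGTNIEKRCR
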