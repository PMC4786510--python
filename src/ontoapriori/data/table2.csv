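Gastric cancer,History of stomach surgery,Milk consumption,Smoking,Family history of gastric cancer
yes,yes,no,yes,yes
yes,yes,no,yes,yes
yes,no,no,yes,yes
yes,yes,yes,no,no
yes,yes,yes,yes,yes
yes,yes,no,yes,yes
no,no,yes,no,yes
no,no,yes,no,no
no,no,yes,no,no
no,no,no,yes,no
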