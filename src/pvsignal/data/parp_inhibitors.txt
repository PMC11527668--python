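# PARP-inhibitor drug dictionary: generic<TAB>synonym (brand name or
# development code).  Every generic is also its own synonym.
Olaparib	Olaparib
Olaparib	Lynparza
Niraparib	Niraparib
Niraparib	Zejula
Rucaparib	Rucaparib
Rucaparib	Rubraca
Talazoparib	Talazoparib
Talazoparib	Talzenna
Veliparib	Veliparib
Veliparib	ABT-888
Pamiparib	Pamiparib
Pamiparib	BaiHuiZe
Pamiparib	BGB-290
Fluzoparib	Fluzoparib
Fluzoparib	AiRuiYi
Fluzoparib	SHR-3162
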