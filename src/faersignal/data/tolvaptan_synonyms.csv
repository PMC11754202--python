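raw_name,canonical_name
amlodipine,amlodipine
aspirin,aspirin
carvedilol,carvedilol
furosemide,furosemide
lisinopril,lisinopril
metformin,metformin
omeprazole,omeprazole
spironolactone,spironolactone
tolvaptan,tolvaptan
TOLVAPTAN,tolvaptan
Tolvaptan,tolvaptan
SAMSCA,tolvaptan
JYNARQUE,tolvaptan
TOLVAPTAN 15MG,tolvaptan
tolvaptan.,tolvaptan
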