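drug	pt	true_rr
tolvaptan	blood creatinine increased	5.0
tolvaptan	blood sodium decreased	25.0
tolvaptan	cardiac failure	5.0
tolvaptan	dehydration	6.0
tolvaptan	hepatic function abnormal	11.0
tolvaptan	hypernatraemia	55.0
tolvaptan	osmotic demyelination syndrome	60.0
tolvaptan	polydipsia	40.0
tolvaptan	polyuria	35.0
tolvaptan	renal cyst ruptured	80.0
tolvaptan	renal impairment	9.0
tolvaptan	thirst	45.0
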