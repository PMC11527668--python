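# MedDRA preferred terms defining the renal adverse-effect query set
# (one PT per line; matching is case-insensitive, whitespace-normalized).
Acute kidney injury
Blood creatinine increased
Blood urea abnormal
Glomerular filtration rate decreased
Renal impairment
Oliguria
Anuria
Dialysis
Hemodialysis
Peritoneal dialysis
Nephropathy toxic
Tubulointerstitial nephritis
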