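# PROSITE patterns used by the annotation cascade, in PROSITE syntax.
# PS00014 (ER_TARGET): C-terminal endoplasmic-reticulum retention signal,
# the KDEL-type tetrapeptide anchored at the C-terminus.
version: 1
patterns:
  PS00014: "[KRHQSA]-[DENQ]-E-L>"
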