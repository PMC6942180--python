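support_level,inclusion,exclusion,total
full,6,5,11
accurate,3,15,18
broad,6,19,25
inaccurate,4,6,10
none,3,7,10
not_applicable,14,7,21
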