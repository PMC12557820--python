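# Target-drug synonym list: brand and generic names, matched after
# uppercasing and whitespace collapsing.
AVACOPAN
TAVNEOS
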