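# Deidentification patterns: PLACEHOLDER <TAB> regex, applied in order.
# Placeholders contain no digits or capitalised name-like runs, so a second
# pass leaves the text unchanged (idempotence).
<EMAIL>	[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}
<PHONE>	\b0\d(?:[ .-]?\d{2}){4}\b
<PHONE>	\+\d{2}[ .-]?\d(?:[ .-]?\d{2}){4}\b
<POSTCODE>	\b\d{5}\b
<NAME>	\b(?:Dr|Mr|Mrs|Ms|Mme|Mlle|M)\.?\s+[A-Z][a-z]+\b
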