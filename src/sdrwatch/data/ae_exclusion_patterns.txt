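# Cues that disqualify a detected medical concept as a potential adverse
# event: one case-insensitive regex per line, with a leading class tag.
# indication: the concept is what the drug treats, not a reaction to it.
# question: the author asks about an effect without reporting it.
# negation: the concept is denied.
# pre_intake: the concept preceded the drug intake.
indication	\bprescribed\b[^.?!]{0,60}\bfor\b
indication	\bto\s+treat\b
indication	\btreatment\s+(?:of|for)\b
indication	\bindicated\s+for\b
question	\?
question	^\s*(?:does|do|did|is|are|can|could|will|would)\b
question	\bi\s+wonder\s+(?:if|whether)\b
negation	\bno\s+(?:sign|trace|symptom)s?\s+of\b
negation	\bnever\s+(?:had|felt|noticed|experienced)\b
negation	\bwithout\s+any\b
pre_intake	\bbefore\s+(?:i\s+)?(?:took|taking|started|starting|using)\b
pre_intake	\balready\s+had\b[^.?!]{0,40}\bbefore\b
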