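# Drug-intake cues: one case-insensitive regex per line.  A message counts
# as an intake message when any pattern matches.  The patterns look for a
# first-person subject attached to an intake verb phrase.
\bi\s+(?:took|take|tried|used|started|stopped)\b
\bi\s+(?:am|was|have\s+been|had\s+been)\s+(?:taking|using|on)\b
\bi(?:'m|\s+am)\s+on\b
\bi\s+was\s+(?:put\s+on|prescribed|given)\b
\bmy\s+(?:doctor|gp|physician)\s+put\s+me\s+on\b
\b(?:my|for\s+my)\s+(?:mother|father|husband|wife|son|daughter)\s+(?:took|takes|is\s+taking|was\s+put\s+on)\b
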