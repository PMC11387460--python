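# Exclusion patterns as printed in the published screening criteria, applied
# identically to both the cetirizine and the loratadine cohort.  A report is
# dropped from the exposed set when any of its drug strings contains one of
# these substrings (case-insensitive).
levocetirizine
reactine
pseudoephedrine hydrochloride
montelukast
linzess
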