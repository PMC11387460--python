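# Corrected exclusion variant for a loratadine cohort: the published list is
# printed identically for both drugs and names "reactine" (a cetirizine brand)
# while omitting desloratadine, which the accompanying prose says was
# excluded.  This variant swaps those; exclusion lists are pure configuration
# and both readings ship so neither has to be guessed.
desloratadine
pseudoephedrine hydrochloride
montelukast
linzess
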