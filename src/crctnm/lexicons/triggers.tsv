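# Default modifier trigger lexicon.
# Columns: pattern <TAB> modifier <TAB> direction <TAB> max_scope_chars
# Patterns match case-insensitively at word boundaries. Edit freely: the
# lists below are a curated default, not a validated clinical resource.

# --- negation -------------------------------------------------------------
no evidence of	negated	forward	120
no evidence for	negated	forward	120
without evidence of	negated	forward	120
no sign of	negated	forward	120
no signs of	negated	forward	120
no convincing evidence of	negated	forward	120
no suspicious	negated	forward	120
no residual	negated	forward	120
no definite	negated	forward	120
no obvious	negated	forward	120
no new	negated	forward	120
no	negated	forward	60
not	negated	forward	60
absence of	negated	forward	120
free of	negated	forward	120
clear of	negated	forward	120
negative for	negated	forward	120
rather than	negated	forward	60
not seen	negated	backward	60
not identified	negated	backward	60
not demonstrated	negated	backward	60
not visualised	negated	backward	60
not visualized	negated	backward	60
ruled out	negated	backward	60
has been excluded	negated	backward	60
is excluded	negated	backward	60
resolved	negated	backward	60

# --- historical -----------------------------------------------------------
history of	historical	forward	120
past history of	historical	forward	120
previous	historical	forward	120
previously	historical	forward	120
prior	historical	forward	120
earlier	historical	forward	120
historic	historical	forward	120
historical	historical	forward	120
in remission	historical	backward	60
previously resected	historical	forward	120
previously excised	historical	forward	120
resected	historical	backward	60
excised	historical	backward	60
treated in	historical	backward	60

# --- general / hypothetical ------------------------------------------------
screening	general	bidirectional	60
screening for	general	forward	120
surveillance	general	bidirectional	60
surveillance for	general	forward	120
risk of	general	forward	120
risk for	general	forward	120
at risk of	general	forward	120
in general	general	backward	60
family history of	general	forward	120
in the event of	general	forward	120
protocol for	general	forward	120

# --- non-definite ----------------------------------------------------------
possible	nondefinite	forward	120
possibly	nondefinite	forward	120
probable	nondefinite	forward	120
probably	nondefinite	forward	120
likely	nondefinite	forward	60
unlikely	nondefinite	forward	60
suspicious for	nondefinite	forward	120
suspicion of	nondefinite	forward	120
suspected	nondefinite	forward	120
suggestive of	nondefinite	forward	120
suggesting	nondefinite	forward	120
query	nondefinite	forward	60
queried	nondefinite	forward	60
may represent	nondefinite	backward	60
could represent	nondefinite	backward	60
cannot exclude	nondefinite	forward	120
cannot be excluded	nondefinite	backward	60
differential includes	nondefinite	forward	120
concerning for	nondefinite	forward	120
equivocal	nondefinite	bidirectional	60
versus	nondefinite	forward	60

# --- metastasis ------------------------------------------------------------
metastasis	metastasis	bidirectional	60
metastases	metastasis	bidirectional	60
metastatic	metastasis	forward	60
metastases from	metastasis	forward	120
metastasis from	metastasis	forward	120
mets	metastasis	bidirectional	60
secondary deposit	metastasis	bidirectional	60
secondary deposits	metastasis	bidirectional	60
oligometastatic	metastasis	forward	60
peritoneal deposits	metastasis	bidirectional	60

# --- recurrence ------------------------------------------------------------
recurrence	recurrence	bidirectional	60
recurrent	recurrence	forward	60
recurrence of	recurrence	forward	120
relapse	recurrence	bidirectional	60
relapsed	recurrence	forward	60
re-growth	recurrence	bidirectional	60
regrowth	recurrence	bidirectional	60

# --- treatment response ----------------------------------------------------
response to	treatment_response	forward	120
responding to	treatment_response	forward	120
treatment response	treatment_response	bidirectional	60
post-treatment	treatment_response	forward	60
post treatment	treatment_response	forward	60
post-chemotherapy	treatment_response	forward	60
post chemoradiotherapy	treatment_response	forward	60
following chemotherapy	treatment_response	forward	120
following chemoradiotherapy	treatment_response	forward	120
regression of	treatment_response	forward	120
regressed	treatment_response	backward	60
downstaged	treatment_response	backward	60
shrinkage of	treatment_response	forward	120
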