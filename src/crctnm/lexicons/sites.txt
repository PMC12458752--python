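# Colorectal anatomical site terms. One per line; matched
# case-insensitively at word boundaries, longest alternative first.
colorectal
colorectum
colon
colonic
sigmoid
sigmoid colon
rectum
rectal
rectosigmoid
rectosigmoid junction
anorectal junction
anorectum
caecum
cecum
caecal
cecal
ileocaecal
ileocecal
ileocaecal valve
ascending colon
descending colon
transverse colon
hepatic flexure
splenic flexure
large bowel
bowel
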