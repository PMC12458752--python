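# Compound colorectal-tumour terms that need no separate site link.
colorectal cancer
colorectal carcinoma
colorectal adenocarcinoma
colorectal tumour
colorectal tumor
colorectal malignancy
colorectal neoplasm
colon cancer
colonic carcinoma
bowel cancer
large bowel cancer
rectal cancer
rectal carcinoma
rectal adenocarcinoma
rectal tumour
sigmoid cancer
caecal cancer
crc
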