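# Tumour keywords. One term per line; matched case-insensitively at word
# boundaries, longest alternative first. A tumour term counts towards
# colorectal cancer only when linked to an anatomical site term in the
# same sentence (or when it appears inside a compound term).
tumour
tumours
tumor
tumors
cancer
cancers
carcinoma
carcinomas
adenocarcinoma
adenocarcinomas
adenoca
malignancy
malignancies
malignant neoplasm
malignant neoplasms
malignant lesion
malignant lesions
malignant mass
malignant masses
malignant tumour
malignant tumor
neoplasm
neoplasms
neoplasia
lesion
lesions
mass
masses
primary
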