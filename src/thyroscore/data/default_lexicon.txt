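# Builtin decomposed subtype vocabulary for thyroid-cancer literature.
#
# [SK]  subtype keywords: one "variant<TAB>canonical subtype code" per line
# [AK]  anatomy keywords: one variant per line
# [MK]  malignancy keywords: one variant per line
#
# Matching is case-insensitive on word boundaries; hyphens count as
# boundaries, so hyphenated variants must be listed explicitly.

[SK]
papillary	PTC
anaplastic	ATC
undifferentiated	ATC
un-differentiated	ATC
follicular	FTC
medullary	MTC

[AK]
thyroid
thyroidal

[MK]
cancer
cancers
carcinoma
carcinomas
tumor
tumors
tumour
tumours
neoplasm
neoplasms
malignancy
malignancies
malignant
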