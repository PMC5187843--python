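"""Reference fold-change tables used as classification fixtures.

Two tables of phasiRNA abundance ratios in soybean serve as a worked
check of the fold-change classifier: per-locus ratios between a wild
(W05) and a cultivated (C08) accession across seven tissues, and
leaf/root ratios across three developmental stages in both accessions.
Such tables are conventionally coloured red at fold change <= 0.5 and
green at fold change >= 2; ``*_LABELS`` freezes those labels
(suppressed / elevated / neutral) for every cell.
"""

# W05/C08 fold change per locus; columns: germinated-seedling aerial (Ga)
# and root (Gr), young-seedling aerial (Ya) and root (Yr), seedling
# primary leaf (Sp), root (Sr), trifoliate (St)
ACCESSION_FC_COLUMNS = ("Ga", "Gr", "Ya", "Yr", "Sp", "Sr", "St")
ACCESSION_FC = {
    "Glyma.04G219600": [1.1, 0.4, 0.6, 1.1, 0.7, 1.2, 0.5],
    "Glyma.06G146200": [1.4, 0.4, 0.9, 1.1, 0.3, 0.6, 0.3],
    "Glyma.06G205100": [1.1, 0.3, 1.4, 0.8, 1.0, 1.5, 0.4],
    "Glyma.06G285500": [1.8, 0.5, 1.6, 1.5, 1.5, 1.2, 1.1],
    "Glyma.08G301200": [0.9, 0.5, 0.5, 0.7, 0.6, 1.0, 0.4],
    "Glyma.12G163000": [0.6, 0.5, 0.9, 1.1, 1.3, 1.1, 0.6],
    "Glyma.13G187900": [3.6, 2.2, 2.5, 2.2, 1.5, 2.3, 3.5],
    "Glyma.11G212800": [0.6, 0.5, 0.6, 1.0, 0.8, 1.5, 0.5],
    "Glyma.07G048000": [2.0, 1.9, 1.8, 2.5, 1.6, 3.2, 1.7],
    "Glyma.16G016600": [1.1, 0.3, 0.4, 1.0, 0.3, 1.1, 0.3],
    "Glyma.09G025300": [1.0, 0.3, 0.9, 1.2, 0.6, 1.4, 1.0],
    "Glyma.16G050500": [2.7, 0.9, 1.0, 0.8, 0.5, 0.7, 1.3],
    "Glyma.16G161900": [1.0, 0.5, 0.8, 1.0, 0.6, 1.2, 0.7],
    "Glyma.16G058900": [1.0, 0.4, 0.9, 1.0, 0.6, 1.1, 0.5],
    "Glyma.16G147100": [0.9, 1.4, 0.6, 1.0, 0.4, 1.1, 0.6],
    "Chr15_44546856_44547257": [0.6, 0.2, 0.6, 0.8, 0.4, 0.9, 0.6],
    "Glyma.09G032400": [1.1, 0.5, 0.7, 0.8, 0.7, 1.0, 0.5],
}
ACCESSION_FC_LABELS = {
    "Glyma.04G219600": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "suppressed"],
    "Glyma.06G146200": ["neutral", "suppressed", "neutral", "neutral", "suppressed", "neutral", "suppressed"],
    "Glyma.06G205100": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "suppressed"],
    "Glyma.06G285500": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "neutral"],
    "Glyma.08G301200": ["neutral", "suppressed", "suppressed", "neutral", "neutral", "neutral", "suppressed"],
    "Glyma.12G163000": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "neutral"],
    "Glyma.13G187900": ["elevated", "elevated", "elevated", "elevated", "neutral", "elevated", "elevated"],
    "Glyma.11G212800": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "suppressed"],
    "Glyma.07G048000": ["elevated", "neutral", "neutral", "elevated", "neutral", "elevated", "neutral"],
    "Glyma.16G016600": ["neutral", "suppressed", "suppressed", "neutral", "suppressed", "neutral", "suppressed"],
    "Glyma.09G025300": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "neutral"],
    "Glyma.16G050500": ["elevated", "neutral", "neutral", "neutral", "suppressed", "neutral", "neutral"],
    "Glyma.16G161900": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "neutral"],
    "Glyma.16G058900": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "suppressed"],
    "Glyma.16G147100": ["neutral", "neutral", "neutral", "neutral", "suppressed", "neutral", "neutral"],
    "Chr15_44546856_44547257": ["neutral", "suppressed", "neutral", "neutral", "suppressed", "neutral", "neutral"],
    "Glyma.09G032400": ["neutral", "suppressed", "neutral", "neutral", "neutral", "neutral", "suppressed"],
}

# leaf/root fold change per locus; columns: germinated seedlings, young
# seedlings, seedlings, and all three stages — each for C08 then W05
TISSUE_FC_COLUMNS = ("G_C08", "G_W05", "Y_C08", "Y_W05",
                     "S_C08", "S_W05", "All_C08", "All_W05")
TISSUE_FC = {
    "Glyma.04G219600": [2.2, 5.4, 2.6, 1.6, 5.3, 3.9, 2.9, 3.0],
    "Glyma.06G146200": [0.8, 1.8, 1.2, 1.0, 2.9, 1.2, 1.4, 1.3],
    "Glyma.06G205100": [0.04, 0.13, 0.01, 0.01, 0.02, 0.02, 0.03, 0.04],
    "Glyma.06G285500": [7.1, 27.9, 6.1, 6.8, 10.6, 13.1, 7.3, 12.0],
    "Glyma.08G301200": [0.1, 0.3, 0.6, 0.4, 1.5, 1.1, 0.5, 0.5],
    "Glyma.12G163000": [19.9, 34.2, 7.0, 6.9, 12.6, 15.6, 11.1, 11.2],
    "Glyma.13G187900": [1.1, 1.4, 1.4, 1.6, 4.8, 2.7, 2.2, 1.9],
    "Glyma.11G212800": [1.2, 1.3, 0.7, 0.4, 1.7, 1.0, 1.2, 0.8],
    "Glyma.07G048000": [1.3, 1.2, 0.4, 0.3, 1.0, 0.6, 0.8, 0.6],
    "Glyma.16G016600": [1.0, 3.2, 1.2, 0.6, 2.5, 0.7, 1.5, 1.2],
    "Glyma.09G025300": [0.4, 1.4, 0.6, 0.5, 1.4, 0.6, 0.7, 0.7],
    "Glyma.16G050500": [0.1, 0.3, 0.3, 0.4, 0.7, 0.5, 0.5, 0.4],
    "Glyma.16G161900": [3.4, 7.5, 2.7, 2.3, 6.8, 3.1, 3.9, 3.9],
    "Glyma.16G058900": [0.8, 1.6, 1.1, 0.9, 2.3, 1.4, 1.1, 1.3],
    "Glyma.16G147100": [0.4, 0.9, 1.0, 0.5, 1.6, 0.8, 0.8, 0.7],
    "Chr15_44546856_44547257": [1.3, 3.8, 3.0, 2.2, 5.8, 2.6, 2.4, 2.9],
    "Glyma.09G032400": [1.3, 2.0, 3.1, 2.7, 4.4, 2.8, 2.5, 2.5],
}
TISSUE_FC_LABELS = {
    "Glyma.04G219600": ["elevated", "elevated", "elevated", "neutral", "elevated", "elevated", "elevated", "elevated"],
    "Glyma.06G146200": ["neutral", "neutral", "neutral", "neutral", "elevated", "neutral", "neutral", "neutral"],
    "Glyma.06G205100": ["suppressed", "suppressed", "suppressed", "suppressed", "suppressed", "suppressed", "suppressed", "suppressed"],
    "Glyma.06G285500": ["elevated", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated"],
    "Glyma.08G301200": ["suppressed", "suppressed", "neutral", "suppressed", "neutral", "neutral", "suppressed", "suppressed"],
    "Glyma.12G163000": ["elevated", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated"],
    "Glyma.13G187900": ["neutral", "neutral", "neutral", "neutral", "elevated", "elevated", "elevated", "neutral"],
    "Glyma.11G212800": ["neutral", "neutral", "neutral", "suppressed", "neutral", "neutral", "neutral", "neutral"],
    "Glyma.07G048000": ["neutral", "neutral", "suppressed", "suppressed", "neutral", "neutral", "neutral", "neutral"],
    "Glyma.16G016600": ["neutral", "elevated", "neutral", "neutral", "elevated", "neutral", "neutral", "neutral"],
    "Glyma.09G025300": ["suppressed", "neutral", "neutral", "suppressed", "neutral", "neutral", "neutral", "neutral"],
    "Glyma.16G050500": ["suppressed", "suppressed", "suppressed", "suppressed", "neutral", "suppressed", "suppressed", "suppressed"],
    "Glyma.16G161900": ["elevated", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated"],
    "Glyma.16G058900": ["neutral", "neutral", "neutral", "neutral", "elevated", "neutral", "neutral", "neutral"],
    "Glyma.16G147100": ["suppressed", "neutral", "neutral", "suppressed", "neutral", "neutral", "neutral", "neutral"],
    "Chr15_44546856_44547257": ["neutral", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated"],
    "Glyma.09G032400": ["neutral", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated", "elevated"],
}
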