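"""Curated activation and inflammation gene sets.

These are the literature-derived reactive/inflammatory signatures used to
score glial activation state: a reactive-astrocyte set, a
disease-associated/activated-microglia set, and a small oligodendrocyte
inflammation set (complement and interleukin genes differentially expressed
in oligodendrocytes over aging).
"""

ASTROCYTE_ACTIVATION = ["C4b", "C3", "Serpina3n", "Cxcl10", "Gfap", "Vim", "Il18", "Hif3a"]

MICROGLIA_ACTIVATION = [
    "B2m",
    "Trem2",
    "Ccl2",
    "Apoe",
    "Axl",
    "Itgax",
    "Cd9",
    "C1qa",
    "C1qc",
    "Lyz2",
    "Ctss",
]

OLIGODENDROCYTE_INFLAMMATION = ["C4b", "Il33", "Il18"]
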