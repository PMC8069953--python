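"""Published reference rows for the drug--target enrichment check.

Each row gives a drug's reversing-target overlap with the 72-gene predicted
candidate set (k), its total target-gene count (n), and the published
p-value against the 10,575-gene meta-analysis/interactome background.
``kind`` records the precision the value was printed at: ``sig3`` = three
significant figures, ``dec3`` = three decimal places.
"""

BACKGROUND_N = 10575
CANDIDATE_K = 72

# (drug, overlap k, targets n, printed p, kind)
ENRICHMENT_ROWS = [
    ("ROVELIZUMAB", 2, 3, 1.37e-4, "sig3"),
    ("DASATINIB", 3, 23, 4.86e-4, "sig3"),
    ("ILORASERTIB", 3, 21, 3.69e-4, "sig3"),
    ("NINTEDANIB", 2, 19, 0.007, "dec3"),
    ("JNJ-26483327", 2, 9, 0.002, "dec3"),
    ("ACALABRUTINIB", 2, 14, 0.004, "dec3"),
    ("IBRUTINIB", 2, 16, 0.005, "dec3"),
    ("XL-228", 2, 16, 0.005, "dec3"),
    ("PEXMETINIB", 2, 12, 0.003, "dec3"),
    ("TG100-801", 2, 16, 0.005, "dec3"),
    ("ENMD-981693", 2, 19, 0.007, "dec3"),
    ("GALLAMINE", 1, 1, 0.007, "dec3"),
    ("AME-133V", 1, 1, 0.007, "dec3"),
    ("ERLIZUMAB", 1, 1, 0.007, "dec3"),
    ("BEMCENTINIB", 1, 1, 0.007, "dec3"),
    ("MILATUZUMAB", 1, 1, 0.007, "dec3"),
    ("ARRY-382", 1, 1, 0.007, "dec3"),
    ("MM-121", 1, 1, 0.007, "dec3"),
    ("PATRITUMAB", 1, 1, 0.007, "dec3"),
    ("BOSUTINIB", 2, 23, 0.011, "dec3"),
    ("BAFETINIB", 1, 2, 0.014, "dec3"),
    ("BACITRACIN", 1, 2, 0.014, "dec3"),
    ("EFALIZUMAB", 1, 2, 0.014, "dec3"),
    ("LIFITEGRAST", 1, 2, 0.014, "dec3"),
    ("BPI-9016", 1, 2, 0.014, "dec3"),
]

# published anti-signature rows: (perturbagen, p, z, combined score)
ANTISIGNATURE_ROWS = [
    ("emetine", 1.40e-11, 1.78, -19.35),
    ("homoharringtonine", 1.32e-10, 1.71, -16.86),
]


def round_sig(x: float, ndigits: int = 3) -> float:
    """Round to ``ndigits`` significant figures."""
    import math

    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (ndigits - 1))


def printed_match(computed: float, printed: float, kind: str) -> bool:
    if kind == "sig3":
        return round_sig(computed, 3) == printed
    return round(computed, 3) == printed
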