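"""Published worked-example inputs: mutation accounting of a teleost TCR
alpha cDNA clone study.

These are *inputs* to the worked examples — per-individual clone counts,
surveyed base pairs and event-class counts for the constant region, and the
printed mono-nucleotide observed/expected mutation counts for the constant
(C alpha) and variable (V alpha) datasets.  All derived quantities
(frequencies per 1,000 bp, R/S ratios, mutability indices, chi-square
significance) are recomputed by the package from these counts, never stored.
"""

# Constant-region mutation accounting per individual:
# clones, surveyed bp, replacement, silent, transitions, transversions, frameshifts
CLONE_SET_COUNTS = {
    "B1": {"clones": 18, "bp": 5690, "repl": 6, "silent": 2,
           "transitions": 7, "transversions": 1, "frameshifts": 2},
    "B4": {"clones": 22, "bp": 6952, "repl": 12, "silent": 4,
           "transitions": 16, "transversions": 0, "frameshifts": 0},
    "B6": {"clones": 39, "bp": 12327, "repl": 8, "silent": 8,
           "transitions": 14, "transversions": 2, "frameshifts": 2},
}

# Mononucleotide observed and composition-expected mutation counts,
# constant-region (C alpha) dataset.
CA_MONO_OBSERVED = {"A": 27, "C": 1, "G": 6, "T": 8}
CA_MONO_EXPECTED = {"A": 10.6, "C": 11.0, "G": 10.0, "T": 8.2}

# Mononucleotide observed/expected counts, variable-region (V alpha) dataset.
VA_MONO_OBSERVED = {"A": 11, "C": 22, "G": 58, "T": 11}
VA_MONO_EXPECTED = {"A": 28.5, "C": 24.6, "G": 22.5, "T": 26.0}

# V alpha substitution spectrum: from-base -> to-base -> count.
VA_SPECTRUM = {
    "A": {"C": 2, "G": 9, "T": 0},
    "C": {"A": 16, "G": 2, "T": 4},
    "G": {"A": 28, "C": 6, "T": 24},
    "T": {"A": 0, "C": 11, "G": 0},
}

# Decimals used by the printed tables (for truncated-report comparison).
CA_MONO_PRINTED_DECIMALS = {"A": 1, "C": 2, "G": 1, "T": 2}
VA_MONO_PRINTED_DECIMALS = {"A": 2, "C": 2, "G": 2, "T": 2}
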