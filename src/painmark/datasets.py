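"""Published summary tables from the chronic-back-pain biomarker study.

These are the printed per-gene results of the human whole-blood microarray
screen (CNBP patients vs healthy controls) and of the rat L5 spinal-nerve-
ligation dorsal-horn validation (qPCR / ddPCR), together with the hand-picked
human-to-rat ortholog mapping used to compare the two species. The raw data
behind these tables were never deposited, so the tables themselves are the
inputs consumed by the refinement gate and the concordance report.
"""

from __future__ import annotations

import pandas as pd

# Human whole-blood screen: gene symbol, two-group ANOVA p, fold-change
# magnitude (linear scale, >= 1), direction of change in patients,
# presence in the compendium correlation analysis (CA), and whether a body
# of pain literature exists for the gene.
_BLOOD_PANEL_ROWS = [
    # gene, p, direction, fc, ca, literature
    ("CASP5", 0.0449, "up", 2.23, False, True),
    ("CLU", 0.0489, "up", 1.85, False, True),
    ("DPP3", 0.0028, "up", 1.50, False, True),
    ("ELF3", 0.0095, "up", 1.62, False, True),
    ("FAM99A", 0.0017, "up", 1.64, False, False),
    ("ICOSLG", 0.0007, "up", 1.20, False, True),
    ("LIN28A", 0.0183, "down", 1.50, False, True),
    ("MC1R", 0.0005, "up", 1.40, False, True),
    ("NLRC4", 0.0437, "up", 1.99, False, True),
    ("ORM2", 0.0225, "up", 1.97, True, False),
    ("ARHGAP11B", 0.0025, "up", 1.57, False, False),
    ("RNF185", 0.0032, "down", 1.68, False, False),
    ("RNU6-76P", 0.0049, "down", 1.54, False, False),
    ("TIMP1", 0.0049, "up", 1.50, True, True),
    ("TLR5", 0.0428, "up", 1.75, False, True),
]

# Rat dorsal-horn validation after L5 SNL (sham n=8 vs SNL n=10), 35 days
# post-surgery. method marks which platform quantified the gene.
_RAT_RESULT_ROWS = [
    # gene, p, direction, fc, method
    ("Casp4", 0.1951, "up", 1.22, "ddpcr"),
    ("Clu", 0.9990, "up", 1.00, "qpcr"),
    ("Dpp3", 0.4670, "down", 1.16, "qpcr"),
    ("Icoslg", 0.7920, "down", 1.16, "qpcr"),
    ("Lin28a", 0.7860, "up", 1.30, "qpcr"),
    ("Mc1r", 0.0847, "up", 2.72, "ddpcr"),
    ("Nlrc4", 0.5242, "up", 1.15, "ddpcr"),
    ("Arhgap11a", 0.8516, "down", 1.03, "ddpcr"),
    ("Rnf185", 0.3900, "down", 2.18, "qpcr"),
    ("Timp1", 0.0058, "up", 2.19, "qpcr"),
    ("Tlr5", 0.6820, "up", 1.51, "qpcr"),
]

# Hand-picked orthologs (or closest related rat gene with high sequence
# similarity, e.g. human CASP5 -> rat Casp4, ARHGAP11B -> Arhgap11a).
# Panel genes without a rat counterpart in the validation set are absent
# here and come out "untestable" in the concordance report.
_ORTHOLOG_ROWS = [
    ("CASP5", "Casp4"),
    ("CLU", "Clu"),
    ("DPP3", "Dpp3"),
    ("ICOSLG", "Icoslg"),
    ("LIN28A", "Lin28a"),
    ("MC1R", "Mc1r"),
    ("NLRC4", "Nlrc4"),
    ("ARHGAP11B", "Arhgap11a"),
    ("RNF185", "Rnf185"),
    ("TIMP1", "Timp1"),
    ("TLR5", "Tlr5"),
]

# Gene symbols shown in the published prior-correlation heatmaps of strongly
# up- and downregulated blood transcripts. TIMP1/ORM2/PROX1 form the highly
# positively correlated triad among the upregulated set.
UPREGULATED_HEATMAP_GENES = [
    "TIMP1", "ORM2", "PROX1", "CST1", "SLC12A9", "CDK17", "ARMCX6",
    "ARHGAP11B", "DPP3", "PSG4", "XAGE5", "OR5M3", "CYP4Z2P", "PHOSPHO1",
    "FAM129C", "ZNF285",
]
DOWNREGULATED_HEATMAP_GENES = [
    "RNF185", "LRRN3", "JAZF1", "PASK", "CETN2", "DRG1", "GSTM2",
    "HIST1H2BK", "NPRL3", "PID1", "ROM1", "SDHD", "TRAPPC6B", "YOD1",
    "C10orf62", "C1orf189",
]


def cnbp_blood_panel() -> pd.DataFrame:
    """Printed 15-gene human blood biomarker panel (CNBP vs controls).

    Returns a DataFrame with columns ``gene, p, direction, fc, ca,
    literature`` — exactly the evidence consumed by
    :func:`painmark.diffexpr.refine_panel`.
    """
    return pd.DataFrame(
        _BLOOD_PANEL_ROWS,
        columns=["gene", "p", "direction", "fc", "ca", "literature"],
    )


def snl_dorsal_horn_results() -> pd.DataFrame:
    """Printed rat dorsal-horn group results (sham vs SNL) per gene."""
    return pd.DataFrame(
        _RAT_RESULT_ROWS, columns=["gene", "p", "direction", "fc", "method"]
    )


def human_rat_ortholog_map() -> pd.DataFrame:
    """Hand-picked human-to-rat ortholog mapping for the validation panel."""
    return pd.DataFrame(_ORTHOLOG_ROWS, columns=["human_gene", "rat_gene"])
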