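"""Published gene rankings used as reference inputs.

Three kinds of lists are shipped:

* ``BULK_TOP15``: top-15 fold-change rankings of the COL11A1-CAF signature
  reported independently for breast (invasive ductal carcinoma vs in situ),
  ovarian (omental metastasis vs primary) and pancreatic (tumor vs normal)
  bulk comparisons.
* ``NORMAL_PANCREAS_TOP30``: the top-30 LUM-seeded attractor genes of each of
  the eleven normal pancreatic samples of a public PDAC single-cell cohort.
* ``ASC_ATTRACTOR_TOP30``: top-30 attractor genes of the adipose stromal
  vascular fraction (SVF) fibroblast population and the consensus attractor
  of the eleven normal pancreatic samples.

These are fixed inputs for overlap statistics, not computed objects.
"""

from __future__ import annotations

BULK_TOP15: dict[str, list[str]] = {
    "breast": [
        "COL11A1", "COL10A1", "MFAP5", "LRRC15", "INHBA",
        "FBN1", "SULF1", "GREM1", "COL5A2", "LOX",
        "COL5A1", "THBS2", "LAMB1", "FAP", "SPOCK",
    ],
    "ovarian": [
        "COL11A1", "COL1A1", "TIMP3", "FN1", "INHBA",
        "EFEMP1", "DSPG3", "COL5A2", "LOX", "MFAP5",
        "POSTN", "COL5A1", "THBS2", "FBN1", "FAP",
    ],
    "pancreatic": [
        "INHBA", "COL10A1", "POSTN", "SULF1", "COL8A1",
        "COL11A1", "CTHRC1", "COL1A1", "THBS2", "HNT",
        "CSPG2", "WISP1", "FN1", "COMP", "COL5A2",
    ],
}

NORMAL_PANCREAS_TOP30: dict[str, list[str]] = {
    "N1": ["DCN", "LUM", "C7", "FBLN1", "MGP", "C1S", "CCDC80", "PTGDS", "DPT",
           "C1R", "APOD", "SEPP1", "FBLN5", "CXCL12", "EFEMP1", "COL1A2",
           "SFRP2", "ALDH1A1", "CFD", "COL6A3", "EMP1", "PCOLCE", "C3", "SRPX",
           "SERPINF1", "ANXA1", "CYR61", "CST3", "RARRES2", "PDGFRA"],
    "N2": ["LUM", "DCN", "C7", "FBLN1", "APOD", "MGP", "C1S", "DPT", "CCDC80",
           "PTGDS", "FBLN5", "SEPP1", "COL1A2", "SFRP2", "SRPX", "SERPINF1",
           "OLFML3", "CST3", "MEG3", "C1R", "MFAP4", "RARRES2", "PCOLCE",
           "CFH", "CXCL12", "FGF7", "PDGFRA", "COL6A3", "ALDH1A1", "SPRY1"],
    "N3": ["LUM", "FBLN1", "C7", "PTGDS", "C1S", "DPT", "PDGFRA", "APOD",
           "SFRP2", "DCN", "CXCL12", "C1R", "COL6A3", "ADH1B", "SPON2", "CFD",
           "LAMA2", "C3", "FBLN5", "ABCA8", "LRP1", "SLIT2", "CFH", "SRPX",
           "COL1A2", "BOC", "FSTL1", "SVEP1", "ABCA9", "CYR61"],
    "N4": ["C7", "FBLN5", "LUM", "DCN", "APOD", "PTGDS", "FBLN1", "C1R", "DPT",
           "SRPX", "FMO2", "SEPP1", "CXCL12", "CYR61", "SFRP2", "CLEC11A",
           "PDGFRA", "NR2F1", "C1S", "ABCA8", "CCDC80", "PTN", "SERPINF1",
           "SVEP1", "CFD", "LAMB1", "FTL", "ANTXR2", "COL6A3", "MGP"],
    "N5": ["APOD", "DPT", "FBLN5", "PDGFRA", "CXCL12", "LUM", "COL6A3",
           "PTGDS", "C7", "CCDC80", "CFD", "MRC2", "FGF7", "SFRP2", "MARCKS",
           "LRP1", "FMO2", "NR2F1", "TNXB", "DCN", "LOX", "C1R", "IGFBP3",
           "HEG1", "RP11-572C15.6", "F3", "ADAMTSL3", "STK17B", "EMP1",
           "MPZL1"],
    "N6": ["LUM", "DCN", "FBLN1", "ADH1B", "DPT", "ABCA8", "C3", "APOD",
           "MMP2", "C1S", "C7", "PTGDS", "SFRP2", "FBLN5", "C1R", "CXCL12",
           "CST3", "MGP", "CCDC80", "MRC2", "COL1A2", "CFD", "SPRY1", "SMOC2",
           "GSN", "COL6A2", "CFH", "OLFML3", "PDGFRA", "PCOLCE"],
    "N7": ["PTGDS", "APOD", "LUM", "FBLN1", "C7", "ADH1B", "DPT", "COL6A3",
           "EFEMP1", "PDGFRA", "CXCL12", "SCN7A", "MMP2", "MEG3", "C1S",
           "OLFML3", "SVEP1", "DCN", "SFRP2", "MRC2", "FBLN5", "C3", "COL1A2",
           "ABCA8", "SRPX", "ACVRL1", "TIMP2", "LAMA2", "DAB2", "NR2F1"],
    "N8": ["C7", "LUM", "DCN", "APOD", "FBLN1", "SFRP2", "PTGDS", "CCDC80",
           "FBLN5", "C1S", "CXCL12", "C3", "CFD", "C1R", "MGP", "CFH",
           "COL6A3", "SRPX", "EFEMP1", "SEPP1", "PDGFRA", "DPT", "CXCL14",
           "ADH1B", "NEGR1", "COL6A2", "BOC", "OLFML3", "EMP1", "LAMA2"],
    "N9": ["DCN", "LUM", "C7", "FBLN1", "APOD", "SFRP2", "SERPINF1", "PTGDS",
           "GSN", "C1S", "SEPP1", "CCDC80", "DPT", "OLFML3", "FBLN5", "C1R",
           "PTN", "MGP", "ALDH1A1", "PDGFRA", "COL6A2", "CST3", "COL6A3",
           "CXCL14", "C3", "CXCL12", "MMP2", "PCOLCE", "IGF1", "ABCA8"],
    "N10": ["MMP2", "APOD", "LUM", "EFEMP1", "CTSK", "SFRP2", "PLTP", "MGST1",
            "LSP1", "FBLN1", "SPON2", "PTGDS", "SVEP1", "CXCL12", "SCN7A",
            "COL6A3", "CCDC80", "COLEC11", "PDGFRA", "HBP1", "CYGB", "ARSK",
            "SH3GL1", "OAF", "BMP1", "LAMA2", "GPC3", "TMEM67", "C1R",
            "PLXDC1"],
    "N11": ["LUM", "DCN", "FBLN1", "SFRP2", "CFD", "APOD", "MGP", "SERPINF1",
            "CCDC80", "C3", "ADH1B", "PTGDS", "C7", "C1S", "CST3", "C1R",
            "CXCL14", "MMP2", "GPNMB", "S100A4", "DPT", "MFAP4", "COL6A2",
            "FBLN5", "SMOC2", "ABCA8", "FMO2", "RP11-572C15.6", "PCOLCE",
            "SEPP1"],
}

ASC_ATTRACTOR_TOP30: dict[str, list[str]] = {
    "adipose_svf": [
        "DCN", "LUM", "APOD", "CFD", "CXCL14", "MGP", "SERPINF1", "GSN",
        "GPX3", "MFAP4", "PLAC9", "S100A13", "IGFBP6", "DPT", "MFAP5", "FOS",
        "MGST1", "COL1A2", "COL6A3", "LAPTM4A", "CXCL12", "WISP2", "SRPX",
        "JUN", "MMP2", "COL6A2", "C1S", "CCDC80", "EGR1", "PCOLCE",
    ],
    "normal_pancreas_consensus": [
        "LUM", "DCN", "FBLN1", "C7", "APOD", "PTGDS", "SFRP2", "C1S",
        "CCDC80", "MGP", "DPT", "CXCL12", "C1R", "FBLN5", "C3", "PDGFRA",
        "SRPX", "COL6A3", "ADH1B", "CFD", "OLFLM3", "SERPINF1", "MMP2",
        "CST3", "SEPP1", "ABCA8", "COL1A2", "LAMB1", "SVEP1", "MEG3",
    ],
}
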