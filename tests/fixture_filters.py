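"""A hand-built 50-gene fixture exercising every filter boundary.

Four B-cell samples; AI values sit exactly on and around each threshold
(abundance 9/10, AI bands 0.09/0.10/0.11 and 0.24/0.25, DNA totals 9/10,
DNA AI 0.24/0.25/0.29/0.30/0.70/0.71/0.75/0.76) so the retained set of
every filter can be enumerated by hand.
"""

import pandas as pd

SAMPLES = ["B1", "B2", "B3", "B4"]


def build_filter_fixture():
    ai_rows = []  # (gene, sample, ai)
    ab_rows = []  # (gene, sample, tmm)
    wes_rows = []  # (gene, maternal, paternal) in one DNA sample

    def gene(name, ai_by_sample, tmm_by_sample=None):
        tmm_by_sample = tmm_by_sample or {s: 50.0 for s in SAMPLES}
        for s in SAMPLES:
            if s in ai_by_sample:
                ai_rows.append((name, s, ai_by_sample[s]))
            ab_rows.append((name, s, tmm_by_sample.get(s, 50.0)))

    def flat(name, ai, tmm=50.0):
        gene(name, {s: ai for s in SAMPLES}, {s: tmm for s in SAMPLES})

    # expression boundary
    gene("exp_below", {s: 0.5 for s in SAMPLES}, {"B1": 9.0, "B2": 50, "B3": 50, "B4": 50})
    flat("exp_at", 0.5, tmm=10.0)

    # nonrandom-bias band (0.1, 0.9), strict, all-samples quantifier
    flat("bias_low_009", 0.09)
    flat("bias_low_010", 0.10)
    flat("bias_low_011", 0.11)
    flat("bias_high_090", 0.90)
    flat("bias_high_091", 0.91)
    gene("bias_partial", {"B1": 0.05, "B2": 0.05, "B3": 0.05, "B4": 0.5})
    gene("bias_missing", {"B1": 0.05, "B2": 0.05, "B3": 0.05})

    # trans-deletion band (0.25, 0.75)
    flat("trans_low_024", 0.24)
    flat("trans_low_025", 0.25)
    gene("trans_three", {"B1": 0.2, "B2": 0.2, "B3": 0.2, "B4": 0.5})
    flat("trans_high_075", 0.75)
    flat("trans_high_076", 0.76)

    # exome totals/bands; RNA side balanced
    for name, maternal, paternal in [
        ("wes_tot9", 5, 4),
        ("wes_tot10", 5, 5),
        ("wes_ai_024", 24, 76),
        ("wes_ai_025", 25, 75),
        ("wes_ai_029", 29, 71),
        ("wes_ai_030", 30, 70),
        ("wes_ai_070", 70, 30),
        ("wes_ai_071", 71, 29),
        ("wes_ai_075", 75, 25),
        ("wes_ai_076", 76, 24),
    ]:
        flat(name, 0.5)
        wes_rows.append((name, maternal, paternal))

    # imprint screen, threshold 0.15 inclusive, expression >= 10 everywhere
    flat("imp_low_005", 0.05)
    flat("imp_low_015", 0.15)
    gene("imp_low_016", {"B1": 0.15, "B2": 0.15, "B3": 0.15, "B4": 0.16})
    flat("imp_high_085", 0.85)
    gene(
        "imp_lowexpr",
        {s: 0.05 for s in SAMPLES},
        {"B1": 9.0, "B2": 50, "B3": 50, "B4": 50},
    )

    n_filler = 50 - len({r[0] for r in ai_rows})
    for i in range(n_filler):
        flat(f"filler_{i:02d}", 0.5)

    ai = pd.DataFrame(ai_rows, columns=["gene_id", "sample_id", "ai"])
    ai["chrom"] = "chr1"
    abundance = pd.DataFrame(ab_rows, columns=["gene_id", "sample_id", "tmm_count"])
    wes = pd.DataFrame(wes_rows, columns=["gene_id", "maternal", "paternal"])
    wes["sample_id"] = "DNA1"
    wes["total"] = wes.maternal + wes.paternal
    wes["ai"] = wes.maternal / wes.total
    return ai, abundance, wes


EXPECTED = {
    # genes removed by the expression filter (min over samples < 10)
    "expression_removed": {"exp_below", "imp_lowexpr"},
    # removed by the (0.1, 0.9) bias rule
    "bias_removed": {"bias_low_009", "bias_high_091", "imp_low_005", "imp_lowexpr"},
    # removed by the (0.25, 0.75) trans rule
    "trans_removed": {
        "trans_low_024",
        "trans_high_076",
        "bias_low_009",
        "bias_low_010",
        "bias_low_011",
        "bias_high_090",
        "bias_high_091",
        "imp_low_005",
        "imp_low_015",
        "imp_low_016",
        "imp_lowexpr",
        "imp_high_085",
    },
    # excluded by the exome rule, default band (0.25, 0.75)
    "wes_excluded_default": {"wes_tot9", "wes_ai_024", "wes_ai_076"},
    # excluded by the exome rule, (0.3, 0.7) dialect
    "wes_excluded_abelson": {
        "wes_tot9",
        "wes_ai_024",
        "wes_ai_025",
        "wes_ai_029",
        "wes_ai_071",
        "wes_ai_075",
        "wes_ai_076",
    },
    # flagged by the imprint screen (threshold 0.15, expression >= 10)
    "imprint_flagged": {"imp_low_005", "imp_low_015", "imp_high_085", "bias_low_009",
                        "bias_low_010", "bias_low_011", "bias_high_090", "bias_high_091"},
}
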