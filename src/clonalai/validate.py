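"""Recovery metrics of a report bundle against a simulated truth table.

Turns a pipeline run on synthetic data into recall/false-discovery numbers
per truth class (escapees, stable-RME genes, imprint-like biases, allelic
losses) plus clonality-classification accuracy, so the whole analysis can
be validated end to end.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from .simulate import StudyTruth


def _recall_fdr(called: set, truth: set) -> Dict[str, float]:
    tp = len(called & truth)
    return {
        "n_true": len(truth),
        "n_called": len(called),
        "true_positives": tp,
        "false_positives": len(called - truth),
        "recall": tp / len(truth) if truth else float("nan"),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
    }


def validate_bundle(bundle: Dict[str, object], truth: StudyTruth, metadata: pd.DataFrame) -> Dict[str, object]:
    """Compare escapee, stable-RME, imprint and LOH results with truth."""
    genes = truth.genes
    metrics: Dict[str, object] = {}

    if "escapees" in bundle:
        calls = bundle["escapees"]
        called = set(calls.loc[calls.call, "gene_id"])
        true_esc = set(genes.loc[genes.ai_class == "escapee", "gene_id"])
        m = _recall_fdr(called, true_esc)
        hit = calls.loc[calls.call & calls.gene_id.isin(true_esc)]
        if len(hit):
            f_true = genes.set_index("gene_id")["xi_fraction"]
            err = (
                hit.set_index("gene_id")["corrected_xi_fraction"]
                - f_true.loc[hit.gene_id]
            )
            m["xi_fraction_mae"] = float(err.abs().mean())
        metrics["escapee"] = m

    if "stable_rme" in bundle:
        calls = bundle["stable_rme"]
        flagged = set(calls.loc[calls.flagged, "gene_id"])
        true_rme = set(genes.loc[genes.ai_class == "stable_rme", "gene_id"])
        metrics["stable_rme"] = _recall_fdr(flagged, true_rme)
        if "wilcoxon_p" in bundle:
            metrics["stable_rme"]["wilcoxon_p"] = float(bundle["wilcoxon_p"])

    if "filter_report" in bundle:
        rep = bundle["filter_report"].to_frame()
        loh_called = set(rep.loc[rep["filter"] == "loh", "gene_id"])
        true_loh = set(genes.loc[genes.ai_class == "loh", "gene_id"])
        metrics["loh"] = _recall_fdr(loh_called, true_loh)

    if "clonality" in bundle:
        calls = bundle["clonality"]
        clon = metadata.set_index("sample_id")["clonality"].to_dict()
        expected = {
            "monoclonal": "monoclonal-consistent",
            "polyclonal": "polyclonal-consistent",
            "unmanipulated": "polyclonal-consistent",
        }
        checked = {s: calls[s] == expected[clon[s]] for s in calls if s in clon}
        metrics["clonality_accuracy"] = (
            sum(checked.values()) / len(checked) if checked else float("nan")
        )

    if "contamination" in bundle and truth.contamination:
        est = bundle["contamination"]
        errs = [
            abs(est[s].c - c) for s, c in truth.contamination.items() if s in est
        ]
        if errs:
            metrics["contamination_mae"] = float(np.mean(errs))

    return metrics
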