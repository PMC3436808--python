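"""Reclassification analysis: reaction types with vs without the capacitance.

Every reaction is labelled excluded / indispensable / variable from its flux
range over the optimal face (flux variability at full optimality), once in
the original model and once after adding the capacitance reaction. The
cross-classification (a 3x3 count matrix, original x augmented) summarizes
how strongly the network rewires: switches between excluded and
indispensable are the dramatic ones.

When the original optimum is 0 (no production at all, as in the packaged
Krebs example), the optimal face is the whole flux polyhedron and the
classification coincides with the blocked-reaction analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import pandas as pd

from .capacitance import Capacitance, augment_model
from .flux_analysis import classify_reactions, flux_variability
from .model import MetabolicModel

__all__ = ["ClassificationTable", "compare_classifications", "render_reports"]

LABELS = ("excluded", "indispensable", "variable")


@dataclass
class ClassificationTable:
    model_name: str
    class_without: dict[str, str]
    class_with: dict[str, str]
    capacitance_class: str  # label of the added reaction itself (no "without" side)
    capacitance_id: str = "SC"

    @property
    def summary(self) -> dict[str, dict[str, int]]:
        """3x3 count matrix: summary[without][with]."""
        counts = {a: {b: 0 for b in LABELS} for a in LABELS}
        for rid, before in self.class_without.items():
            counts[before][self.class_with[rid]] += 1
        return counts

    def switches(self, before: str, after: str) -> list[str]:
        return sorted(
            rid
            for rid, b in self.class_without.items()
            if b == before and self.class_with[rid] == after
        )

    def trend_checks(self) -> dict[str, bool]:
        """Three qualitative trends of the reclassification.

        (i) fewer reactions become newly indispensable than stop being
        indispensable; (ii) fewer become newly excluded than stop being
        excluded; (iii) fewer excluded->indispensable switches than
        indispensable->excluded switches.
        """
        s = self.summary
        new_ind = s["excluded"]["indispensable"] + s["variable"]["indispensable"]
        lost_ind = s["indispensable"]["excluded"] + s["indispensable"]["variable"]
        new_exc = s["indispensable"]["excluded"] + s["variable"]["excluded"]
        lost_exc = s["excluded"]["indispensable"] + s["excluded"]["variable"]
        return {
            "fewer_new_indispensable": new_ind <= lost_ind,
            "fewer_new_excluded": new_exc <= lost_exc,
            "fewer_excluded_to_indispensable": s["excluded"]["indispensable"]
            <= s["indispensable"]["excluded"],
        }


def compare_classifications(
    model: MetabolicModel,
    cap: Capacitance,
    flux_bound: float | None = None,
    tol: float = 1e-6,
) -> ClassificationTable:
    """Classify every reaction before and after adding the capacitance.

    A trivial capacitance (empty support) leaves the model unchanged, so both
    classifications coincide by construction. ``flux_bound`` defaults to a
    per-component scaling consistent with the capacitance search (lambda /
    max |r_i| is the caller's responsibility; the default 1000 matches the
    default search bound).
    """
    records = flux_variability(model, optimality_fraction=1.0)
    before = classify_reactions(records, tol)
    if cap.is_trivial or cap.r_int is None:
        return ClassificationTable(
            model.name, before, dict(before), capacitance_class="excluded"
        )
    if flux_bound is None:
        flux_bound = 1000.0 / max(abs(v) for v in cap.r_int.values())
    augmented = augment_model(model, cap.r_int, flux_bound, reaction_id="SC")
    records_after = flux_variability(augmented, optimality_fraction=1.0)
    after_all = classify_reactions(records_after, tol)
    cap_class = after_all.pop("SC")
    return ClassificationTable(model.name, before, after_all, cap_class)


def render_reports(table: ClassificationTable) -> tuple[pd.DataFrame, str]:
    """Per-reaction TSV-ready table and a JSON summary string.

    The DataFrame has stable columns (reaction, class_without, class_with);
    the JSON carries the 3x3 summary, the capacitance's own label and the
    trend booleans, and parses back to the same counts.
    """
    df = pd.DataFrame(
        {
            "reaction": list(table.class_without),
            "class_without": [table.class_without[r] for r in table.class_without],
            "class_with": [table.class_with[r] for r in table.class_without],
        }
    )
    payload = {
        "model": table.model_name,
        "summary": table.summary,
        "capacitance_reaction": {
            "id": table.capacitance_id,
            "class_with": table.capacitance_class,
        },
        "trends": table.trend_checks(),
        "n_reactions": len(table.class_without),
    }
    return df, json.dumps(payload, indent=2)
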