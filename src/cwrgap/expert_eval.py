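"""Concordance between expert priority scores and gap-analysis results.

Crop experts score each taxon's collecting urgency on the same 0-10 scale as
the final priority score (FPS): a comparable EPS restricted to the evidence
the gap analysis uses, and a contextual EPS drawing on wider knowledge
(in situ threats, breeding usefulness).  This module averages the expert
scores per taxon, maps them onto the FPS priority categories, and reports a
simple linear agreement index on a 0 (disagreement) to 100 (agreement)
scale: 100 x (1 - |mean EPS - FPS| / 10).  The index is a documented,
configurable surrogate for richer multi-factor accord analyses that need
per-expert evaluation variables beyond the two EPS kinds.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .gap_analysis import fps_and_category


class ExpertError(ValueError):
    pass


@dataclass
class ConcordanceReport:
    per_taxon: pd.DataFrame  # mean EPS, categories, differences, index
    mean_comparable_eps: float
    mean_contextual_eps: float
    mean_abs_difference: float  # mean |mean comparable EPS - FPS|
    mean_agreement_index: float
    crosstab: pd.DataFrame  # gap category x expert category counts


def _category_of(score: float) -> str:
    # reuse the FPS thresholds; a zero score is treated as high priority
    _, cat = fps_and_category(score, score, score, G=1 if score > 0 else 0)
    return cat


def agreement_index(mean_eps: float, fps: float) -> float:
    """100 x (1 - |mean EPS - FPS| / 10), clipped to [0, 100]."""
    return max(0.0, min(100.0, 100.0 * (1.0 - abs(mean_eps - fps) / 10.0)))


def concordance(
    expert_table: pd.DataFrame, gap_scores: pd.DataFrame
) -> ConcordanceReport:
    """Per-taxon expert/gap comparison.

    ``expert_table`` needs columns expert, taxon, comparable_eps,
    contextual_eps; ``gap_scores`` needs taxon, FPS (category optional —
    recomputed from FPS when absent).  Every taxon scored by experts must
    exist in the gap results.
    """
    required = {"expert", "taxon", "comparable_eps", "contextual_eps"}
    missing = required - set(expert_table.columns)
    if missing:
        raise ExpertError(f"expert table missing columns: {sorted(missing)}")
    gap = gap_scores.set_index("taxon")
    unknown = sorted(set(expert_table["taxon"]) - set(gap.index))
    if unknown:
        raise ExpertError(f"taxa missing from gap scores: {unknown}")

    rows = []
    for taxon, grp in expert_table.groupby("taxon", sort=False):
        mean_comp = float(grp["comparable_eps"].mean())
        mean_ctx = float(grp["contextual_eps"].mean())
        fps = float(gap.loc[taxon, "FPS"])
        gap_cat = (
            str(gap.loc[taxon, "category"])
            if "category" in gap.columns
            else _category_of(fps)
        )
        rows.append(
            {
                "taxon": taxon,
                "mean_comparable_eps": mean_comp,
                "mean_contextual_eps": mean_ctx,
                "expert_category": _category_of(mean_comp),
                "FPS": fps,
                "gap_category": gap_cat,
                "abs_difference": abs(mean_comp - fps),
                "agreement_index": agreement_index(mean_comp, fps),
            }
        )
    per_taxon = pd.DataFrame(rows)
    crosstab = pd.crosstab(per_taxon["gap_category"], per_taxon["expert_category"])
    return ConcordanceReport(
        per_taxon=per_taxon,
        mean_comparable_eps=float(per_taxon["mean_comparable_eps"].mean()),
        mean_contextual_eps=float(per_taxon["mean_contextual_eps"].mean()),
        mean_abs_difference=float(per_taxon["abs_difference"].mean()),
        mean_agreement_index=float(per_taxon["agreement_index"].mean()),
        crosstab=crosstab,
    )
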