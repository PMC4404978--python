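"""Simulated expert evaluation of the gap-analysis priorities.

Generates expert priority scores anchored on each species' FPS with
realistic disagreement noise, then reports per-species concordance and the
0-100 agreement index.
"""

import pandas as pd

from common import EXPERT_NOISE_SD, N_EXPERTS, RESULTS, SEED
from cwrgap.expert_eval import concordance
from cwrgap.synthetic import generate_expert_scores


def main() -> None:
    gap = pd.read_csv(RESULTS / "gap_scores.csv")
    experts = generate_expert_scores(gap, n_experts=N_EXPERTS,
                                     noise_sd=EXPERT_NOISE_SD, seed=SEED + 60)
    experts.to_csv(RESULTS / "expert_scores.csv", index=False)
    report = concordance(experts, gap)
    report.per_taxon.to_csv(RESULTS / "concordance.csv", index=False)
    print(report.per_taxon.round(2).to_string(index=False))
    print(f"mean comparable EPS {report.mean_comparable_eps:.2f}; "
          f"mean |EPS - FPS| {report.mean_abs_difference:.2f}; "
          f"mean agreement index {report.mean_agreement_index:.1f}/100")
    print("category cross-tabulation (gap rows x expert columns):")
    print(report.crosstab.to_string())


if __name__ == "__main__":
    main()
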