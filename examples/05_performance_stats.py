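"""Aphid performance metrics and summary-statistics t tests.

Computes larval relative growth rate and the intrinsic rate of increase
from raw assay quantities, and compares two lines' performance from
printed-table summaries (mean ± SE, n) alone.
"""

from symbiofba import (
    GroupSummary,
    intrinsic_rate,
    pooled_t_summary,
    relative_growth_rate,
)

rgr = relative_growth_rate(w_day2=0.18, w_day7=1.24)
print(f"RGR for 0.18 mg -> 1.24 mg over the 5-day assay: {rgr:.4f} mg·mg⁻¹·day⁻¹")

r_m = intrinsic_rate(Md=50, d=9.0)
print(f"r_m for 50 progeny, first reproduction at day 9: {r_m:.4f} day⁻¹")

res = pooled_t_summary(
    GroupSummary(mean=0.351, se=0.005, n=10),
    GroupSummary(mean=0.347, se=0.010, n=10),
)
print(
    f"\ncarrier 0.351±0.005 vs cured 0.347±0.010 (n=10 each): "
    f"t_{res.df:.0f} = {res.statistic:.3f}, p = {res.p:.3f}"
)
print(
    "\nThe tiny t statistic says symbiont carriage costs no measurable\n"
    "reproductive performance — the premise for attributing downstream\n"
    "metabolic differences to the symbiont rather than to host condition."
)
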