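"""Reference summary statistics and their re-analysis.

Published per-condition summary statistics (group mean and standard
deviation, n = 8 plants per condition) for the terminal submovement counts
and endpoint variability of pea tendrils climbing an artificial pole (AC)
versus a biological host stem (BC). Group size is inferred from the
reported t-test degrees of freedom (df = 14).

:func:`reference_ttests` re-derives the between-condition pooled Student t
statistics and Cohen's d from these summaries alone — no raw trajectories
are needed — via :func:`tendrilkin.groupstats.student_t_pooled`.
"""

from __future__ import annotations

import pandas as pd

from .groupstats import student_t_pooled

REFERENCE_GROUP_SIZE = 8

# measure -> condition -> (mean, sd)
REFERENCE_SUBMOVEMENT_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "submovement_velocity": {"BC": (48.000, 13.148), "AC": (67.125, 20.490)},
    "submovement_acceleration": {"BC": (26.250, 7.025), "AC": (43.250, 21.684)},
    "submovement_jerk": {"BC": (37.500, 7.982), "AC": (59.375, 26.403)},
    "total_submovements": {"BC": (115.500, 23.513), "AC": (169.750, 63.209)},
    "endpoint_variability": {"BC": (18.072, 11.294), "AC": (242.397, 45.776)},
}


def reference_ttests(measures: list[str] | None = None) -> pd.DataFrame:
    """BC-vs-AC pooled t tests recomputed from the shipped summaries.

    One row per measure: t, df, p, Cohen's d with large-sample SE and 95% CI.
    The contrast is BC minus AC (matching the sign convention the summary
    table's source analysis used), so higher AC counts give negative t and d.
    """
    if measures is None:
        measures = [m for m in REFERENCE_SUBMOVEMENT_SUMMARY
                    if m != "endpoint_variability"]
    rows = []
    n = REFERENCE_GROUP_SIZE
    for measure in measures:
        groups = REFERENCE_SUBMOVEMENT_SUMMARY[measure]
        (m_bc, sd_bc), (m_ac, sd_ac) = groups["BC"], groups["AC"]
        res = student_t_pooled(n, m_bc, sd_bc, n, m_ac, sd_ac, labels=("BC", "AC"))
        rows.append(
            {
                "measure": measure,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
                "cohens_d": res.effect_size,
                "cohens_d_se": res.effect_se,
                "d_ci_low": res.effect_ci_low,
                "d_ci_high": res.effect_ci_high,
            }
        )
    return pd.DataFrame(rows)


__all__ = ["REFERENCE_GROUP_SIZE", "REFERENCE_SUBMOVEMENT_SUMMARY", "reference_ttests"]
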