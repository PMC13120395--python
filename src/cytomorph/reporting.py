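"""Cohort-level statistical reports.

Builds the baseline comparison table (median [IQR] per group,
Mann-Whitney p, Cliff's delta with bootstrap CI), the sex odds ratios in
both orientations, and the exposed-group Spearman correlation matrix —
the full battery applied to an exposure cohort.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .study_data import Cohort

logger = logging.getLogger(__name__)

#: continuous variables compared between groups, in report order
BASELINE_VARIABLES = ("age", "smoker_owners", "cigarettes_per_day")
#: exposed-group correlation variables, in report order
CORRELATION_VARIABLES = ("cotinine_ng_ml", "case_nc_ratio",
                         "inflammation_score", "dysplasia_grade", "age")


def group_comparison_table(cohort: Cohort,
                           variables: Optional[Sequence[str]] = None, *,
                           bootstrap_reps: int = 10_000, rng_seed: int = 0
                           ) -> pd.DataFrame:
    """One row per continuous variable: exposed vs non-exposed.

    Variables missing on every record are skipped; ``case_nc_ratio`` and
    ``cotinine_ng_ml`` are appended automatically when present.
    """
    df = cohort.to_frame()
    if not len(cohort.exposed) or not len(cohort.non_exposed):
        raise st.ValidationError("group comparison needs both exposure groups")
    if variables is None:
        variables = list(BASELINE_VARIABLES)
        for extra in ("case_nc_ratio", "cotinine_ng_ml"):
            if df[extra].notna().any():
                variables.append(extra)
    rows = []
    for var in variables:
        sub = df[["exposure", var]].dropna()
        x = sub.loc[sub.exposure == "exposed", var].to_numpy(float)
        y = sub.loc[sub.exposure == "non_exposed", var].to_numpy(float)
        if x.size == 0 or y.size == 0:
            logger.warning("variable %s has no data in one group; skipped",
                           var)
            continue
        gc = st.compare_groups(x, y, var, bootstrap_reps=bootstrap_reps,
                               rng_seed=rng_seed)
        rows.append({
            "variable": var, "n_exposed": gc.n1, "n_non_exposed": gc.n2,
            "median_exposed": gc.median1, "iqr_exposed": gc.iqr1,
            "median_non_exposed": gc.median2, "iqr_non_exposed": gc.iqr2,
            "u_statistic": gc.u_statistic, "p_value": gc.p_value,
            "cliffs_delta": gc.cliffs_delta,
            "delta_ci_low": gc.delta_ci[0], "delta_ci_high": gc.delta_ci[1],
        })
    return pd.DataFrame(rows)


def sex_odds_ratios(cohort: Cohort, *, ci_method: str = "exact") -> dict:
    """Fisher's exact test on sex by exposure, in both orientations.

    ``female``: table [[exposed F, exposed M], [non-exposed F,
    non-exposed M]]; ``male`` is the column-swapped table, whose OR is
    the reciprocal.
    """
    f_e = sum(1 for r in cohort.exposed if r.sex == "F")
    m_e = len(cohort.exposed) - f_e
    f_n = sum(1 for r in cohort.non_exposed if r.sex == "F")
    m_n = len(cohort.non_exposed) - f_n
    return {
        "female": st.fisher_exact_2x2([[f_e, m_e], [f_n, m_n]],
                                      ci_method=ci_method),
        "male": st.fisher_exact_2x2([[m_e, f_e], [m_n, f_n]],
                                    ci_method=ci_method),
    }


def exposed_correlations(cohort: Cohort,
                         variables: Sequence[str] = CORRELATION_VARIABLES
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation matrix over the exposed animals with complete
    data on all requested variables."""
    df = cohort.to_frame()
    exposed = df[df.exposure == "exposed"]
    return st.correlation_matrix(exposed, variables)


def cotinine_nc_association(cohort: Cohort) -> st.SpearmanResult:
    """Spearman rho with Fisher-z CI between urinary cotinine and case
    N/C within the exposed animals that have both measurements."""
    df = cohort.to_frame()
    exposed = df[df.exposure == "exposed"]
    return st.spearman_with_ci(exposed["cotinine_ng_ml"].to_numpy(float),
                               exposed["case_nc_ratio"].to_numpy(float))
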