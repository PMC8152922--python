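"""Per-subject fitting pipeline tying the psychometric stages together."""

from __future__ import annotations

import pandas as pd

from .psychometric import (
    PsychFit,
    fit_crossed,
    fit_uncrossed,
    reversal_summary,
    tabulate_judgments,
)
from .synthetic import TOJSession


def fit_subject(
    uncrossed: TOJSession,
    crossed: TOJSession,
    n_starts: int = 20,
    seed=0,
    grid_step_ms: float = 1.0,
) -> dict:
    """Fit both sessions of one subject and summarise the reversal.

    Returns a flat record (dict) with the sigmoid and flip parameters,
    goodness-of-fit of both fits, the reversal value and mean peak flip
    — one row of the per-cohort fit table.
    """
    if uncrossed.condition != "uncrossed" or crossed.condition != "crossed":
        raise ValueError("sessions passed in the wrong order")
    u_fit = fit_uncrossed(tabulate_judgments(uncrossed), n_starts=n_starts, seed=seed)
    c_fit = fit_crossed(
        tabulate_judgments(crossed), u_fit, n_starts=n_starts, seed=seed
    )
    summary = reversal_summary(c_fit, u_fit, grid_step_ms=grid_step_ms)
    sig, flp = u_fit.params, c_fit.params
    return {
        "subject": uncrossed.subject,
        "p_max": sig.p_max,
        "p_min": sig.p_min,
        "sigma_u": sig.sigma_u,
        "d_u": sig.d_u,
        "a_l": flp.a_l,
        "a_r": flp.a_r,
        "sigma_f": flp.sigma_f,
        "d": flp.d,
        "c": flp.c,
        "uncrossed_chi2": u_fit.chi2,
        "uncrossed_df": u_fit.df,
        "uncrossed_p": u_fit.p_value,
        "uncrossed_r2": u_fit.r_squared,
        "crossed_chi2": c_fit.chi2,
        "crossed_df": c_fit.df,
        "crossed_p": c_fit.p_value,
        "crossed_r2": c_fit.r_squared,
        "accepted": u_fit.accepted and c_fit.accepted,
        "reversal_value": summary.reversal_value,
        "mean_peak_flip": summary.mean_peak_flip,
    }


def fit_cohort(sessions, n_starts: int = 20, seed=0) -> pd.DataFrame:
    """Fit every subject that has both sessions; one row per subject."""
    by_subject: dict[str, dict[str, TOJSession]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject, {})[s.condition] = s
    rows = []
    for i, (subject, pair) in enumerate(sorted(by_subject.items())):
        if {"uncrossed", "crossed"} - set(pair):
            raise ValueError(f"subject {subject} lacks one of the two sessions")
        rows.append(
            fit_subject(pair["uncrossed"], pair["crossed"], n_starts=n_starts, seed=seed + i)
        )
    return pd.DataFrame(rows)
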