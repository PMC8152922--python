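"""Exhaustive feature-subset search for the best probit model of reversal.

Every combination of up to ``max_size`` candidate cortical features
(optionally each with and without an additive sex indicator) is fitted
by :func:`tojcortex.probit.fit_probit` and scored by PSIS-LOO. The best
model is the one with the lowest LOOIC among models whose Pareto-k
diagnostics are all below 0.7; models failing that reliability rule stay
in the ranking but cannot win.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .loo import LooResult, psis_loo
from .probit import PosteriorDraws, SamplerConfig, fit_probit

__all__ = ["ModelScore", "SearchResult", "search_models", "n_subset_models"]


@dataclass(frozen=True)
class ModelScore:
    """One evaluated feature subset."""

    features: tuple
    with_sex: bool
    loo: LooResult
    rhat_max: float

    @property
    def looic(self) -> float:
        return self.loo.looic


@dataclass
class SearchResult:
    """Ranked feature subsets with the selected best model (if any)."""

    models: list[ModelScore]
    best: ModelScore | None

    def ranking(self) -> pd.DataFrame:
        rows = [
            {
                "features": "+".join(str(f) for f in m.features)
                + ("+sex" if m.with_sex else ""),
                "n_features": len(m.features) + int(m.with_sex),
                "elpd_loo": m.loo.elpd_loo,
                "looic": m.loo.looic,
                "max_pareto_k": m.loo.max_pareto_k,
                "ok": m.loo.ok,
                "rhat_max": m.rhat_max,
            }
            for m in sorted(self.models, key=lambda m: m.looic)
        ]
        return pd.DataFrame(rows)


def n_subset_models(n_candidates: int, max_size: int, include_sex: bool = False) -> int:
    """Number of models an exhaustive search evaluates."""
    from math import comb

    total = sum(comb(n_candidates, s) for s in range(1, max_size + 1))
    return total * (2 if include_sex else 1)


def search_models(
    candidates,
    outcome,
    feature_frame: pd.DataFrame,
    max_size: int = 8,
    include_sex: bool = False,
    seed=0,
    config: SamplerConfig | None = None,
) -> SearchResult:
    """Fit and LOO-score every candidate-feature subset up to ``max_size``.

    Parameters
    ----------
    candidates
        Feature identifiers; each must be a column of ``feature_frame``.
        Typically the region x metric pairs flagged by the association
        screen.
    outcome
        Per-subject reversal values aligned with ``feature_frame`` rows.
    feature_frame
        Per-subject feature values; a ``sex`` column (0/1) is required
        when ``include_sex`` is set, and is appended to each subset
        rather than counted against ``max_size``.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    if not 1 <= max_size <= 8:
        raise ValueError("max_size must be in 1..8")
    missing = [c for c in candidates if c not in feature_frame.columns]
    if missing:
        raise ValueError(f"candidates not in feature frame: {missing}")
    if include_sex and "sex" not in feature_frame.columns:
        raise ValueError("include_sex requires a 'sex' column")

    y = np.asarray(outcome, dtype=float)
    seed_seq = np.random.SeedSequence(seed)
    sex_options = (False, True) if include_sex else (False,)

    models: list[ModelScore] = []
    subsets = [
        combo
        for size in range(1, min(max_size, len(candidates)) + 1)
        for combo in combinations(candidates, size)
    ]
    child_seeds = seed_seq.spawn(len(subsets) * len(sex_options))
    i = 0
    for combo in subsets:
        for with_sex in sex_options:
            cols = list(combo) + (["sex"] if with_sex else [])
            x = feature_frame[cols].to_numpy(dtype=float)
            fit_seed = int(child_seeds[i].generate_state(1)[0] % (2**31))
            i += 1
            draws = fit_probit(cols, y, x, config=config, seed=fit_seed)
            models.append(
                ModelScore(
                    features=tuple(combo),
                    with_sex=with_sex,
                    loo=psis_loo(draws),
                    rhat_max=float(draws.rhat.max()),
                )
            )
    eligible = [m for m in models if m.loo.ok]
    best = min(eligible, key=lambda m: m.looic) if eligible else None
    return SearchResult(models=models, best=best)
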