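"""Ground-truth validation experiments for the whole pipeline.

Each function runs a self-contained simulation study — generate data
with known parameters, run the corresponding analysis stage, measure the
recovery — and returns plain numbers. They back both the test suite and
the reproducibility script, so the same experiment definitions are used
everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtr

from . import synthetic
from .morphometry import region_metrics
from .pipeline import fit_cohort
from .probit import SamplerConfig, _pointwise_loglik, fit_probit, standardize_features
from .psychometric import (
    FlipParams,
    JudgmentTable,
    SigmoidParams,
    evaluate_flip,
    evaluate_sigmoid,
    reversal_summary,
)
from .loo import psis_loo
from .selection import search_models

__all__ = [
    "simulate_binomial_tables",
    "flip_recovery_experiment",
    "probit_recovery_experiment",
    "psis_vs_exact_loo",
    "planted_pair_search",
    "icosphere_rsi",
    "simulate_toj_study",
]

#: light-but-valid sampler settings used by the simulation studies
LIGHT_SAMPLER = SamplerConfig(chains=2, warmup=600, draws=500)

STUDY_SIGMOID = SigmoidParams(p_max=0.98, p_min=0.02, sigma_u=50.0, d_u=5.0)
STUDY_FLIP = FlipParams(a_l=0.5, a_r=0.4, sigma_f=200.0, d=0.0, c=0.2)


def simulate_binomial_tables(
    sigmoid: SigmoidParams, flip: FlipParams, reps: int, rng
) -> tuple[JudgmentTable, JudgmentTable]:
    """Binomial per-SOA count tables for both conditions at ``reps``/level."""
    soa_u = np.asarray(synthetic.UNCROSSED_LEVELS)
    soa_c = np.asarray(synthetic.CROSSED_LEVELS)
    p_u = np.asarray(evaluate_sigmoid(sigmoid, soa_u))
    p_c = np.asarray(evaluate_flip(flip, sigmoid, soa_c))
    return (
        JudgmentTable(soa_u, np.full(soa_u.size, reps), rng.binomial(reps, p_u)),
        JudgmentTable(soa_c, np.full(soa_c.size, reps), rng.binomial(reps, p_c)),
    )


def flip_recovery_experiment(
    seed: int, reps: int = 400, n_boot: int = 30
) -> dict[str, np.ndarray]:
    """Recover the five flip parameters by MLE at ``reps`` repetitions/level.

    Standard errors come from a parametric bootstrap (``n_boot``
    re-simulations at the generating parameters, refitted with a lighter
    multi-start). Returns the estimate, truth, SE and z-score vectors in
    the order (A_l, A_r, sigma_f, d, c).
    """
    from .psychometric import fit_crossed, fit_uncrossed

    truth = np.array(
        [STUDY_FLIP.a_l, STUDY_FLIP.a_r, STUDY_FLIP.sigma_f, STUDY_FLIP.d, STUDY_FLIP.c]
    )
    rng = np.random.default_rng(seed)

    def one_fit(n_starts, fit_seed):
        tab_u, tab_c = simulate_binomial_tables(STUDY_SIGMOID, STUDY_FLIP, reps, rng)
        u = fit_uncrossed(tab_u, n_starts=n_starts, seed=fit_seed)
        c = fit_crossed(tab_c, u, n_starts=n_starts, seed=fit_seed + 1)
        p = c.params
        return np.array([p.a_l, p.a_r, p.sigma_f, p.d, p.c])

    est = one_fit(20, seed)
    boots = np.array([one_fit(10, seed + 10 * (b + 1)) for b in range(n_boot)])
    se = boots.std(axis=0, ddof=1)
    return {"estimate": est, "truth": truth, "se": se, "z": (est - truth) / se}


def probit_recovery_experiment(seed: int, n: int = 200) -> dict[str, np.ndarray]:
    """Posterior-mean recovery of (alpha_1, alpha_2, C, sigma_obs) at n=200."""
    rng = np.random.default_rng(seed)
    x = standardize_features(rng.normal(size=(n, 2)))
    truth = np.array([0.8, -0.5, 0.1, 0.02])
    y = np.clip(ndtr(x @ truth[:2] + truth[2]) + rng.normal(0, truth[3], n), 0, 1)
    draws = fit_probit(
        ("f1", "f2"),
        y,
        x,
        SamplerConfig(chains=4, warmup=1000, draws=1000),
        seed=seed,
        standardize=False,
    )
    est = np.r_[draws.coefficients.mean(0), draws.intercept.mean(), draws.sigma_obs.mean()]
    sd = np.r_[draws.coefficients.std(0), draws.intercept.std(), draws.sigma_obs.std()]
    return {"estimate": est, "truth": truth, "posterior_sd": sd, "z": (est - truth) / sd}


def psis_vs_exact_loo(seed: int, n: int = 8) -> dict[str, float]:
    """PSIS-LOO against brute-force exact leave-one-out refits.

    An n=8, one-feature model on an evenly spaced design with moderate
    observation noise: every subject is refitted out once and its exact
    log predictive density is averaged over the refit posterior.
    """
    rng = np.random.default_rng(seed)
    x = standardize_features(np.linspace(-1.0, 1.0, n)[:, None])
    y = np.clip(ndtr(0.5 * x[:, 0]) + rng.normal(0, 0.25, n), 0, 1)
    cfg = SamplerConfig(chains=4, warmup=1500, draws=3000)
    full = fit_probit(("f",), y, x, cfg, seed=seed, standardize=False)
    approx = psis_loo(full)
    exact = 0.0
    for s in range(n):
        keep = np.arange(n) != s
        refit = fit_probit(("f",), y[keep], x[keep], cfg, seed=seed + 100 + s, standardize=False)
        ll = _pointwise_loglik(
            y[s : s + 1], x[s : s + 1], refit.coefficients, refit.intercept, refit.sigma_obs
        )
        exact += float(logsumexp(ll[0]) - np.log(ll.shape[1]))
    return {
        "elpd_psis": approx.elpd_loo,
        "elpd_exact": exact,
        "abs_diff": abs(approx.elpd_loo - exact),
        "max_pareto_k": approx.max_pareto_k,
    }


def planted_pair_search(
    seed: int, n_repeats: int = 10, n: int = 120, n_candidates: int = 5
) -> dict[str, float]:
    """How often the subset search selects a strongly coupled feature pair.

    Each repeat simulates a cohort whose outcome is driven by the first
    two of five candidate features (coefficients 0.9 and -0.7, noise sd
    0.05) and runs the exhaustive search up to pairs.
    """
    hits = 0
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        raw = rng.normal(size=(n, n_candidates))
        z = standardize_features(raw)
        y = np.clip(ndtr(0.9 * z[:, 0] - 0.7 * z[:, 1]) + rng.normal(0, 0.05, n), 0, 1)
        frame = pd.DataFrame(raw, columns=[f"f{i}" for i in range(n_candidates)])
        res = search_models(
            list(frame.columns), y, frame, max_size=2, seed=seed + 1000 + r,
            config=LIGHT_SAMPLER,
        )
        if res.best is not None and set(res.best.features) == {"f0", "f1"}:
            hits += 1
    return {"selected": hits, "repeats": n_repeats, "rate": hits / n_repeats}


def icosphere_rsi(subdivisions: int = 3) -> float:
    """RSI of a discretized unit sphere (|H| = 1 everywhere): ~4 pi.

    Vertex areas follow the one-third-of-surrounding-triangles rule on a
    subdivided icosahedron.
    """
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertex_area = np.zeros(len(mesh.vertices))
    for face, area in zip(mesh.faces, mesh.area_faces):
        vertex_area[face] += area / 3.0
    table = pd.DataFrame(
        {
            "region": "sphere",
            "thickness_mm": 1.0,
            "area_mm2": vertex_area,
            "mean_curv_per_mm": 1.0,
        }
    )
    return float(region_metrics(table).loc[0, "rsi"])


def simulate_toj_study(
    n_subjects: int = 42, seed: int = 0, reps: int = 8, n_starts: int = 20
) -> pd.DataFrame:
    """Simulate and fit a full behavioural cohort under the study design.

    Subjects span the observed range of crossed-hands behaviour: good
    uncrossed sigmoids with heterogeneous flip amplitude, width and
    constant offset. Returns the fitted cohort table joined with each
    subject's generating reversal value.
    """
    rng = np.random.default_rng(seed)
    sessions = []
    truth_rows = []
    for i in range(n_subjects):
        sigmoid = SigmoidParams(
            p_max=float(rng.uniform(0.93, 1.0)),
            p_min=float(rng.uniform(0.0, 0.07)),
            sigma_u=float(rng.uniform(25, 90)),
            d_u=float(rng.uniform(-25, 25)),
        )
        flip = FlipParams(
            a_l=float(rng.uniform(0.0, 0.8)),
            a_r=float(rng.uniform(0.0, 0.8)),
            sigma_f=float(rng.uniform(80, 400)),
            d=float(rng.uniform(-60, 60)),
            c=float(rng.uniform(0.0, 0.6)),
        )
        subject = synthetic.GroundTruthSubject(
            id=f"sub-{i + 1:03d}",
            sex="F" if rng.random() < 19 / 42 else "M",
            sigmoid=sigmoid,
            flip=flip,
            seed=int(rng.integers(2**31)),
        )
        for k, condition in enumerate(("uncrossed", "crossed")):
            schedule = synthetic.make_soa_schedule(condition, reps, 16, seed=subject.seed + k)
            sessions.append(
                synthetic.simulate_toj_session(subject, schedule, seed=subject.seed + 2 + k)
            )
        truth_rows.append(
            {
                "subject": subject.id,
                "sex": subject.sex,
                "true_reversal_value": reversal_summary(flip, sigmoid).reversal_value,
                "true_mean_peak_flip": 0.5 * (flip.a_l + flip.a_r),
            }
        )
    fits = fit_cohort(sessions, n_starts=n_starts, seed=seed)
    return fits.merge(pd.DataFrame(truth_rows), on="subject")
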