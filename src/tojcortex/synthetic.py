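"""Synthetic TOJ sessions and cortical cohorts with known ground truth.

Every downstream stage of the pipeline — psychometric fitting, region
morphometry, the correlation screen and probit model selection — is
validated by parameter recovery on data generated here, so the generator
mirrors the study design exactly: the uncrossed session samples 12
signed SOAs (+/-15, 30, 60, 100, 200, 300 ms) and the crossed session 14
(+/-30, 60, 100, 200, 300, 450, 900 ms), each repeated 8 times, plus 16
catch trials at a 100 ms SOA per session (112 and 128 trials in total).

The cortical generator emits per-subject, per-vertex tables over the 68
Desikan-Killiany regions whose region-level aggregates (MCT, RSI) equal
drawn ground-truth values exactly, and couples a chosen feature set to a
latent reversal value through the same probit link the model-selection
stage fits, so the generative and analysis directions match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DK_REGIONS, hemisphere_of
from .psychometric import (
    FlipParams,
    SigmoidParams,
    evaluate_flip,
    evaluate_sigmoid,
)

__all__ = [
    "UNCROSSED_LEVELS",
    "CROSSED_LEVELS",
    "CATCH_SOA_MS",
    "SOA_DOMAIN",
    "SOASchedule",
    "GroundTruthSubject",
    "CortexSpec",
    "make_soa_schedule",
    "simulate_toj_session",
    "simulate_cohort",
    "TOJSession",
]

UNCROSSED_LEVELS: tuple[float, ...] = tuple(
    float(s * v) for v in (15, 30, 60, 100, 200, 300) for s in (-1, 1)
)
CROSSED_LEVELS: tuple[float, ...] = tuple(
    float(s * v) for v in (30, 60, 100, 200, 300, 450, 900) for s in (-1, 1)
)
CATCH_SOA_MS = 100.0

#: SOAs outside this span (ms) are outside the curves' evaluation domain.
SOA_DOMAIN = (-900.0, 900.0)

_LEVELS = {"uncrossed": UNCROSSED_LEVELS, "crossed": CROSSED_LEVELS}


@dataclass(frozen=True)
class SOASchedule:
    """A shuffled trial list for one TOJ session."""

    condition: str
    soa_levels: tuple[float, ...]
    reps_per_level: int
    catch_count: int
    catch_soa: float
    #: ordered (soa_ms, is_catch, catch_hand) triples; catch_hand is ''
    #: for normal trials and 'L'/'R' for catch trials.
    trials: tuple[tuple[float, bool, str], ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_normal(self) -> int:
        return len(self.soa_levels) * self.reps_per_level


@dataclass(frozen=True)
class GroundTruthSubject:
    """Generating psychometric parameters for one simulated participant."""

    id: str
    sex: str
    sigmoid: SigmoidParams
    flip: FlipParams
    seed: int

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class TOJSession:
    """Trial-level responses for one participant in one condition."""

    subject: str
    condition: str
    trials: pd.DataFrame  # trial_index, soa_ms, is_catch, response_left_second


def make_soa_schedule(
    condition: str, reps_per_level: int = 8, catch_count: int = 16, seed=0
) -> SOASchedule:
    """Build and shuffle the trial list for one session.

    Defaults reproduce the study design: 8 repetitions per signed SOA and
    16 catch trials give 112 uncrossed (96 normal) and 128 crossed trials.
    """
    if condition not in _LEVELS:
        raise ValueError(f"unknown condition {condition!r}; expected 'uncrossed' or 'crossed'")
    if reps_per_level < 0 or catch_count < 0:
        raise ValueError("reps_per_level and catch_count must be >= 0")
    levels = _LEVELS[condition]
    rng = np.random.default_rng(seed)
    trials: list[tuple[float, bool, str]] = [
        (soa, False, "") for soa in levels for _ in range(reps_per_level)
    ]
    trials += [
        (CATCH_SOA_MS, True, ("L", "R")[rng.integers(2)]) for _ in range(catch_count)
    ]
    order = rng.permutation(len(trials))
    return SOASchedule(
        condition=condition,
        soa_levels=levels,
        reps_per_level=reps_per_level,
        catch_count=catch_count,
        catch_soa=CATCH_SOA_MS,
        trials=tuple(trials[i] for i in order),
    )


def simulate_toj_session(
    subject: GroundTruthSubject, schedule: SOASchedule, seed=0
) -> TOJSession:
    """Draw one session's responses from the subject's generating curves.

    Each non-catch response is a Bernoulli draw with probability from the
    uncrossed sigmoid or the crossed flip curve at the trial's SOA. Catch
    trials (both stimuli to one hand) get the deterministic correct
    response to the second stimulus and never enter the fitted counts.
    """
    rng = np.random.default_rng(seed)
    lo, hi = SOA_DOMAIN
    rows = []
    for idx, (soa, is_catch, catch_hand) in enumerate(schedule.trials):
        if is_catch:
            # second stimulus lands on the catch hand -> correct response
            resp = 1 if catch_hand == "L" else 0
        else:
            if not lo <= soa <= hi:
                raise ValueError(f"SOA {soa} ms outside evaluation domain {SOA_DOMAIN}")
            if schedule.condition == "uncrossed":
                p = evaluate_sigmoid(subject.sigmoid, soa)
            else:
                p = evaluate_flip(subject.flip, subject.sigmoid, soa)
            resp = int(rng.random() < p)
        rows.append((idx, soa, is_catch, resp))
    trials = pd.DataFrame(
        rows, columns=["trial_index", "soa_ms", "is_catch", "response_left_second"]
    )
    return TOJSession(subject=subject.id, condition=schedule.condition, trials=trials)


# ---------------------------------------------------------------------------
# Cortical cohorts


@dataclass(frozen=True)
class ProbitCoupling:
    """Generative probit link from standardized cortical features to the
    latent reversal value: g(sum_i alpha_i F_i + C), g the standard
    normal CDF."""

    feature_ids: tuple[tuple[str, str], ...]  # (region, metric) pairs
    coefficients: tuple[float, ...]
    intercept: float = 0.0
    sex_coefficient: float = 0.0  # additive effect of the female indicator

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.coefficients):
            raise ValueError("one coefficient per feature required")


@dataclass(frozen=True)
class CortexSpec:
    """Population description of a synthetic cortical cohort.

    Region metric scales are loosely calibrated to adult FreeSurfer
    morphometry: MCT ~ 2.5 mm, vertex |H| ~ 0.13 mm^-1, vertex area
    ~ 0.6 mm^2; between-subject spread a few percent of the mean.
    """

    region_labels: tuple[str, ...] = DK_REGIONS
    vertices_per_region: int = 60
    mct_mean_mm: float = 2.5
    mct_sd_mm: float = 0.12
    vertex_thickness_sd_mm: float = 0.3
    vertex_abs_curv_mean: float = 0.13
    vertex_abs_curv_sd: float = 0.04
    vertex_area_mean_mm2: float = 0.6
    rsi_rel_sd: float = 0.06
    coupling: ProbitCoupling | None = None
    obs_noise_sd: float = 0.05
    female_fraction: float = 19 / 42
    vida_fraction: float = 12 / 42

    def __post_init__(self) -> None:
        labels = self.region_labels
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be distinct")
        if self.vertices_per_region < 1:
            raise ValueError("vertices_per_region must be >= 1")
        for name in ("mct_sd_mm", "vertex_thickness_sd_mm", "rsi_rel_sd", "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.coupling is not None:
            known_metrics = {"mct", "rsi", "ratio", "volume"}
            for region, metric in self.coupling.feature_ids:
                if region not in labels:
                    raise ValueError(f"coupling references unknown region {region!r}")
                if metric not in known_metrics:
                    raise ValueError(f"coupling references unknown metric {metric!r}")

    @property
    def rsi_mean(self) -> float:
        # expected sum |H| dA over a region
        return self.vertices_per_region * self.vertex_abs_curv_mean * self.vertex_area_mean_mm2

    def region_population_means(self) -> pd.DataFrame:
        """Per-region population means of MCT and RSI.

        Regions differ in their population mean (a fixed, spec-derived
        pattern, identical for every cohort seed) so that region
        identity matters; subjects vary around these means.
        """
        rng = np.random.default_rng(1234)  # fixed: part of the population spec
        n = len(self.region_labels)
        return pd.DataFrame(
            {
                "region": list(self.region_labels),
                "mct_mean": self.mct_mean_mm + rng.normal(0.0, 0.15, n),
                "rsi_mean": self.rsi_mean * (1.0 + rng.normal(0.0, 0.10, n)),
            }
        )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant feature")
    return (x - x.mean()) / sd


def simulate_cohort(
    spec: CortexSpec, n_subjects: int, seed=0
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate a cohort of subjects with linked cortex and reversal values.

    Per subject and region, ground-truth MCT and RSI are drawn from the
    spec's population distributions; vertex-level tables are constructed
    so that aggregation recovers the drawn values exactly (thickness is
    re-centred to the drawn MCT; vertex areas are rescaled so
    sum |H| dA equals the drawn RSI). The latent reversal value is
    g(sum alpha_i z(F_i) + C) plus Gaussian observation noise, clipped
    to [0, 1]; features are z-scored across the cohort before coupling.

    Returns
    -------
    subjects : DataFrame with id, sex, scanner, true_reversal_value
    vertex_tables : dict subject id -> per-vertex DataFrame
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    from scipy.special import ndtr  # local import keeps numpy-only fast path

    rng = np.random.default_rng(seed)
    regions = spec.region_labels
    n_regions = len(regions)
    nv = spec.vertices_per_region

    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_subjects)]
    sex = np.where(rng.random(n_subjects) < spec.female_fraction, "F", "M")
    scanner = np.where(rng.random(n_subjects) < spec.vida_fraction, "vida", "prisma")

    # region-specific population means (a fixed CortexSpec property,
    # independent of the cohort seed)
    pop = spec.region_population_means()
    mct_region_means = pop["mct_mean"].to_numpy()
    rsi_region_means = pop["rsi_mean"].to_numpy()

    mct = np.maximum(
        0.5, mct_region_means + rng.normal(0.0, spec.mct_sd_mm, (n_subjects, n_regions))
    )
    rsi = np.maximum(
        1e-3,
        rsi_region_means * (1.0 + rng.normal(0.0, spec.rsi_rel_sd, (n_subjects, n_regions))),
    )

    vertex_tables: dict[str, pd.DataFrame] = {}
    volume = np.empty((n_subjects, n_regions))
    for s, sid in enumerate(subject_ids):
        cols: dict[str, np.ndarray] = {}
        thick_all = np.empty(n_regions * nv)
        area_all = np.empty(n_regions * nv)
        curv_all = np.empty(n_regions * nv)
        for r in range(n_regions):
            sl = slice(r * nv, (r + 1) * nv)
            t = np.maximum(
                0.0, rng.normal(mct[s, r], spec.vertex_thickness_sd_mm, nv)
            )
            t += mct[s, r] - t.mean()  # aggregate recovers the drawn MCT exactly
            h = np.abs(rng.normal(spec.vertex_abs_curv_mean, spec.vertex_abs_curv_sd, nv))
            h = np.maximum(h, 1e-4)
            a = np.maximum(1e-4, rng.normal(spec.vertex_area_mean_mm2, 0.1, nv))
            a *= rsi[s, r] / float(np.sum(h * a))  # sum |H| dA recovers the drawn RSI
            thick_all[sl], area_all[sl], curv_all[sl] = t, a, h
            volume[s, r] = float(np.sum(a * t))
        vertex_tables[sid] = pd.DataFrame(
            {
                "subject": sid,
                "hemi": np.repeat([hemisphere_of(r) for r in regions], nv),
                "region": np.repeat(regions, nv),
                "vertex_id": np.tile(np.arange(nv), n_regions),
                "thickness_mm": thick_all,
                "area_mm2": area_all,
                "mean_curv_per_mm": curv_all,
            }
        )

    metric_arrays = {"mct": mct, "rsi": rsi, "ratio": rsi / mct, "volume": volume}
    if spec.coupling is None:
        eta = np.zeros(n_subjects)
    else:
        eta = np.full(n_subjects, spec.coupling.intercept, dtype=float)
        for (region, metric), alpha in zip(
            spec.coupling.feature_ids, spec.coupling.coefficients
        ):
            r = regions.index(region)
            eta += alpha * _zscore(metric_arrays[metric][:, r])
        eta += spec.coupling.sex_coefficient * (sex == "F").astype(float)
    true_reversal = np.clip(
        ndtr(eta) + rng.normal(0.0, spec.obs_noise_sd, n_subjects), 0.0, 1.0
    )

    subjects = pd.DataFrame(
        {
            "id": subject_ids,
            "sex": sex,
            "scanner": scanner,
            "true_reversal_value": true_reversal,
        }
    )
    return subjects, vertex_tables
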