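"""Synthetic cohorts with the statistical structure of a population study of
autonomic function (24-h HRV) and beta-cell response (OGTT).

Two fidelity levels:

* **score level** — a standardized linear-Gaussian structural-equation model
  (SEM) over an exposure composite, one or more outcome composites and a set
  of confounders.  Path coefficients are solved in closed form so that the
  population crude and covariate-adjusted regression coefficients equal
  requested targets exactly; this mode is cheap at large n and is what the
  association machinery is validated against.
* **signal level** — per-subject raw data: a 24-h labelled beat series with
  circadian, low-frequency (~0.1 Hz) and high-frequency (~0.25 Hz)
  modulation scaled by a latent autonomic score, and a 7-point OGTT whose
  C-peptide curve is forward-simulated from the beta-cell secretion model
  through two-compartment kinetics.  This mode exercises the metric
  extraction code end to end.

Reproducibility: every draw is a pure function of (configuration, seed);
per-subject substreams are keyed by (master seed, subject index) so subject
k is identical regardless of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import betacell
from .hrv import ARTIFACT, ECTOPIC, SINUS, BeatSeries

__all__ = [
    "ConfounderPath",
    "SEMConfig",
    "solve_sem_paths",
    "calibrate_ladder_sem",
    "draw_cohort_scores",
    "draw_antithetic_pair",
    "score_level_composites",
    "draw_covariates",
    "SubjectTruth",
    "draw_subject_truths",
    "ModulationSpec",
    "synthesize_beat_series",
    "synthesize_ogtt",
    "GLUCOSE_TEMPLATES",
    "LADDER_BLOCKS",
    "subject_rng",
]

GMS_LEVELS = ("NGM", "prediabetes", "T2D")
GMS_PROPS = (0.60, 0.16, 0.24)


def subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    """Per-subject substream keyed by (master seed, subject index)."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed), int(subject_index))))


# ---------------------------------------------------------------------------
# score-level structural-equation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfounderPath:
    """One standardized confounder: paths to the exposure and to each outcome.

    ``ladder_block`` names the adjustment-ladder stage at which the
    confounder is first controlled (used by the ladder calibration).
    """

    name: str
    a: float  # path confounder -> exposure
    b: Mapping[str, float]  # outcome name -> path confounder -> outcome
    ladder_block: str = ""

    def __post_init__(self) -> None:
        if abs(self.a) >= 1:
            raise ValueError(f"|a| must be < 1 for {self.name}")
        for k, v in self.b.items():
            if abs(v) >= 1:
                raise ValueError(f"|b[{k}]| must be < 1 for {self.name}")


@dataclass(frozen=True)
class SEMConfig:
    """Standardized linear-Gaussian SEM: X = sum a_i C_i + e_x;
    Y_j = d_j X + sum b_ij C_i + e_j; all nodes unit variance.

    Residual SDs are solved from the standardization constraint, not free.
    """

    n_subjects: int
    exposure: str
    direct_effects: Mapping[str, float]  # outcome name -> d_j
    confounders: Sequence[ConfounderPath] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name, d in self.direct_effects.items():
            if abs(d) >= 1:
                raise ValueError(f"|direct effect| must be < 1 for outcome {name}")
        self.residual_sd_exposure()  # raises if infeasible
        for name in self.direct_effects:
            self.residual_sd_outcome(name)

    # -- closed-form population quantities ---------------------------------
    def residual_sd_exposure(self) -> float:
        v = 1.0 - sum(c.a**2 for c in self.confounders)
        if v <= 0:
            raise ValueError("exposure paths imply non-positive residual variance")
        return float(np.sqrt(v))

    def residual_sd_outcome(self, outcome: str) -> float:
        d = self.direct_effects[outcome]
        ab = sum(c.a * c.b.get(outcome, 0.0) for c in self.confounders)
        v = 1.0 - (d**2 + sum(c.b.get(outcome, 0.0) ** 2 for c in self.confounders) + 2 * d * ab)
        if v <= 0:
            raise ValueError(f"outcome {outcome!r} paths imply non-positive residual variance")
        return float(np.sqrt(v))

    def population_crude(self, outcome: str) -> float:
        """Population regression of Y_j on X (var X = 1): d_j + sum a_i b_ij."""
        d = self.direct_effects[outcome]
        return float(d + sum(c.a * c.b.get(outcome, 0.0) for c in self.confounders))

    def population_adjusted(self, outcome: str, controlled: Sequence[str] | None = None) -> float:
        """Population coefficient of Y_j on X controlling the named confounders.

        ``controlled=None`` (default) controls every confounder; an explicit
        empty sequence controls none (and reproduces the crude coefficient).
        Confounders are mutually independent, so each uncontrolled one
        contributes its a_i * b_ij product on top of the direct effect.
        """
        controlled = (
            {c.name for c in self.confounders} if controlled is None else set(controlled)
        )
        d = self.direct_effects[outcome]
        left = sum(
            c.a * c.b.get(outcome, 0.0) for c in self.confounders if c.name not in controlled
        )
        return float(d + left)


def solve_sem_paths(
    crude_target: float,
    adjusted_target: float,
    confounder_spec: Sequence[tuple[str, float, float]],
    outcome: str = "outcome",
    exposure: str = "exposure",
    n_subjects: int = 2007,
    seed: int = 0,
) -> SEMConfig:
    """Solve SEM paths so population crude / adjusted coefficients hit targets.

    ``confounder_spec`` lists (name, a_i, b_weight_i); the direct effect is
    set to the adjusted target and the outcome-side paths are scaled so that
    sum a_i b_i equals the crude-adjusted gap:  crude = d + sum a_i b_i.
    """
    if abs(crude_target) >= 1 or abs(adjusted_target) >= 1:
        raise ValueError("standardized targets must have magnitude < 1")
    gap = crude_target - adjusted_target
    denom = sum(a * w for _, a, w in confounder_spec)
    if gap != 0 and denom == 0:
        raise ValueError("confounder spec cannot produce a crude-adjusted gap")
    scale = 0.0 if gap == 0 else gap / denom
    confs = [
        ConfounderPath(name=name, a=a, b={outcome: w * scale})
        for name, a, w in confounder_spec
    ]
    return SEMConfig(
        n_subjects=n_subjects,
        exposure=exposure,
        direct_effects={outcome: adjusted_target},
        confounders=confs,
        seed=seed,
    )


#: Confounders of the adjustment ladder that carry SEM paths, with the
#: ladder stage at which each is first controlled and its exposure-side path.
LADDER_BLOCKS = (
    ("age", "m1", 0.25),
    ("matsuda", "m2", 0.35),
    ("chol_hdl_ratio", "m3a", 0.20),
    ("bmi", "m3a", 0.30),
    ("sbp", "m3b", 0.20),
)

LADDER_ORDER = ("crude", "m1", "m2", "m3a", "m3b")


def calibrate_ladder_sem(
    exposure: str,
    ladder_targets: Mapping[str, Mapping[str, float]],
    n_subjects: int = 2007,
    seed: int = 0,
) -> SEMConfig:
    """SEM calibrated to a full adjustment ladder for one or more outcomes.

    ``ladder_targets[outcome]`` maps model ids (subset of crude/m1/m2/m3a/
    m3b, in per-SD-*lower*-exposure sign convention, i.e. as printed) to the
    target standardized coefficient.  Internally the exposure is oriented
    "higher is better", so paths use the negated targets; the association
    ladder's inversion step restores the printed sign.

    Each ladder stage controls one block of confounders; the block's summed
    a_i * b_ij product equals the drop in the population coefficient at that
    stage, so every stage of the ladder is calibrated, not just the ends.
    """
    direct: dict[str, float] = {}
    b_by_conf: dict[str, dict[str, float]] = {name: {} for name, _, _ in LADDER_BLOCKS}
    for outcome, targets in ladder_targets.items():
        t = {k: -float(v) for k, v in targets.items()}  # printed -> internal sign
        if "m3b" not in t or "crude" not in t:
            raise ValueError("ladder targets need at least 'crude' and 'm3b'")
        # fill unspecified intermediate stages by linear interpolation
        seq = [t["crude"]]
        known = [t.get(m) for m in LADDER_ORDER[1:]]
        for i, v in enumerate(known):
            if v is None:
                nxt = next(x for x in known[i + 1 :] if x is not None)
                known[i] = seq[-1] + (nxt - seq[-1]) / 2.0
            seq.append(known[i])
        direct[outcome] = seq[-1]
        # stage drops -> per-block products
        stages = dict(zip(LADDER_ORDER[1:], np.diff(seq) * -1.0))
        for stage in LADDER_ORDER[1:]:
            block = [(n, a) for n, s, a in LADDER_BLOCKS if s == stage]
            for name, a in block:
                b_by_conf[name][outcome] = stages[stage] / len(block) / a
    confs = [
        ConfounderPath(name=name, a=a, b=b_by_conf[name], ladder_block=stage)
        for name, stage, a in LADDER_BLOCKS
    ]
    return SEMConfig(
        n_subjects=n_subjects, exposure=exposure, direct_effects=direct,
        confounders=confs, seed=seed,
    )


#: Affine display scales for score-mode covariates: column -> (mean, sd).
#: Affine maps keep the SEM's adjustment structure exact; realistic skewed
#: marginals belong to the signal-level generator.
SCORE_COVARIATE_SCALES = {
    "age": (60.0, 8.0),
    "matsuda": (3.46, 1.6),
    "chol_hdl_ratio": (3.6, 1.1),
    "bmi": (26.7, 4.2),
    "sbp": (134.6, 17.9),
}


def _draw_score_frames(config: SEMConfig, include_extras: bool, antithetic: bool):
    n = config.n_subjects
    min_rows = 3 + len(config.confounders) + len(config.direct_effects)
    if n < min_rows:
        raise ValueError(f"n_subjects={n} too small for the model ({min_rows} terms)")
    rng = np.random.default_rng(config.seed)
    C = {c.name: rng.standard_normal(n) for c in config.confounders}
    x = rng.standard_normal(n) * config.residual_sd_exposure()
    for c in config.confounders:
        x = x + c.a * C[c.name]
    eps = {
        name: rng.standard_normal(n) * config.residual_sd_outcome(name)
        for name in config.direct_effects
    }
    extras: dict = {}
    if include_extras:
        extras["sex"] = np.where(rng.random(n) < 0.52, "M", "F")
        extras["education"] = rng.choice(["low", "middle", "high"], n, p=[0.32, 0.27, 0.41])
        extras["smoking"] = rng.choice(["never", "former", "current"], n, p=[0.34, 0.53, 0.13])
        extras["alcohol"] = rng.choice(["none", "low", "high"], n, p=[0.17, 0.56, 0.27])
        extras["lipid_med"] = (rng.random(n) < 0.33).astype(int)
        extras["antihypertensive_med"] = (rng.random(n) < 0.37).astype(int)
        extras["gms"] = rng.choice(list(GMS_LEVELS), n, p=list(GMS_PROPS))

    frames = []
    for sign in (1.0, -1.0) if antithetic else (1.0,):
        out = {config.exposure: x}
        for name, d in config.direct_effects.items():
            y = sign * eps[name] + d * x
            for c in config.confounders:
                y = y + c.b.get(name, 0.0) * C[c.name]
            out[name] = y
        df = pd.DataFrame(out)
        for c in config.confounders:
            mu, sd = SCORE_COVARIATE_SCALES.get(c.name, (0.0, 1.0))
            df[c.name] = mu + sd * C[c.name]
        for k, v in extras.items():
            df[k] = v
        df.index.name = "subject_id"
        frames.append(df)
    return frames


def draw_cohort_scores(config: SEMConfig, include_extras: bool = True) -> pd.DataFrame:
    """Draw a score-level cohort from the SEM.

    Returns one row per subject with the exposure composite, each outcome
    composite, the path-carrying confounders (on affine display scales) and
    — when ``include_extras`` — the zero-path categorical covariates the
    adjustment ladder also controls (sex, education, smoking, alcohol,
    medication flags, glucose-metabolism status).
    """
    return _draw_score_frames(config, include_extras, antithetic=False)[0]


def draw_antithetic_pair(
    config: SEMConfig, include_extras: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A cohort and its antithetic twin (outcome residuals sign-flipped).

    Both cohorts share the exposure, confounders and covariates; only the
    structural residual of each outcome equation changes sign.  Averaging an
    estimate over the pair cancels the first-order Monte-Carlo noise of a
    regression coefficient, so calibration summaries converge much faster
    than with independent draws at the same cost.
    """
    a, b = _draw_score_frames(config, include_extras, antithetic=True)
    return a, b


# ---------------------------------------------------------------------------
# covariate marginals (signal-level realism, Table-1-like)
# ---------------------------------------------------------------------------


def _age_parent_params(mean: float = 60.0, sd: float = 8.0, lo: float = 40.0, hi: float = 75.0):
    """Parent-normal (mu, sigma) whose [lo, hi] truncation has the given moments."""

    def eqs(p):
        mu, sig = p
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(eqs, x0=[mean, sd * 1.3], full_output=False)
    return float(sol[0]), float(sol[1])


_AGE_PARENT = _age_parent_params()


def draw_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Cohort covariate table with realistic marginals.

    Age is a moment-matched truncated normal (realized mean 60 / SD 8 on
    [40, 75]); sex is 52% men; glucose-metabolism status is 60/16/24%
    NGM / prediabetes / T2D.  Metabolic covariates get documented mild
    shifts by glucose-metabolism status (higher BMI, blood pressure and
    medication use, lower insulin sensitivity in T2D); the full joint
    correlation structure of the source population is not reproduced.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mu, sig = _AGE_PARENT
    a, b = (40.0 - mu) / sig, (75.0 - mu) / sig
    age = stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)
    sex = np.where(rng.random(n) < 0.52, "M", "F")
    gms = rng.choice(list(GMS_LEVELS), n, p=list(GMS_PROPS))
    t2d = gms == "T2D"
    pre = gms == "prediabetes"

    bmi = rng.normal(26.0, 3.8, n) + 2.5 * t2d + 1.0 * pre
    bmi = np.clip(bmi, 16.0, 55.0)
    sbp = rng.normal(132.0, 17.0, n) + 8.0 * t2d + 4.0 * pre
    matsuda = np.exp(rng.normal(np.log(4.2), 0.62, n) - 0.9 * t2d - 0.45 * pre)
    chol_hdl = np.exp(rng.normal(np.log(3.5), 0.30, n) + 0.05 * t2d)
    egfr = np.clip(rng.normal(89.0, 14.0, n) - 3.0 * t2d, 15.0, 140.0)

    df = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "gms": gms,
            "education": rng.choice(["low", "middle", "high"], n, p=[0.32, 0.27, 0.41]),
            "smoking": rng.choice(["never", "former", "current"], n, p=[0.34, 0.53, 0.13]),
            "alcohol": rng.choice(["none", "low", "high"], n, p=[0.17, 0.56, 0.27]),
            "bmi": bmi,
            "waist": np.clip(rng.normal(92.0, 11.0, n) + 6.0 * t2d + 2.0 * pre, 55, 160),
            "sbp": sbp,
            "matsuda": matsuda,
            "chol_hdl_ratio": chol_hdl,
            "egfr": egfr,
            "lipid_med": (rng.random(n) < np.where(t2d, 0.60, 0.25)).astype(int),
            "antihypertensive_med": (rng.random(n) < np.where(t2d, 0.60, 0.30)).astype(int),
            "insulin_use": (t2d & (rng.random(n) < 0.20)).astype(int),
            "energy_intake_kj": np.clip(rng.normal(9215.0, 2553.0, n), 2000, 25000),
            "physical_activity_h": np.clip(rng.normal(14.3, 8.1, n), 0.0, 24.0),
            "cvd_history": (rng.random(n) < 0.16).astype(int),
        }
    )
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# subject-level ground truth and raw-signal synthesis
# ---------------------------------------------------------------------------

#: Per-class 7-point glucose excursion templates (mmol/L at the OGTT times);
#: fixed piecewise-linear shapes, editable in configuration.
GLUCOSE_TEMPLATES = {
    "NGM": np.array([5.0, 6.6, 7.8, 7.9, 7.2, 6.1, 5.4]),
    "prediabetes": np.array([5.9, 7.7, 9.2, 9.5, 9.1, 7.9, 7.0]),
    "T2D": np.array([7.6, 9.3, 10.9, 11.7, 12.1, 12.2, 11.8]),
}

#: Hepatic-extraction-like plasma insulin / C-peptide concentration ratio per
#: class; prediabetes highest (hyperinsulinaemic compensation).
INSULIN_CP_RATIO = {"NGM": 0.12, "prediabetes": 0.20, "T2D": 0.10}


@dataclass(frozen=True)
class SubjectTruth:
    """Generator ground truth for one synthetic subject."""

    subject_id: str
    latent_autonomic: float  # z-score driving HRV modulation amplitudes
    gms: str
    glucose_sensitivity: float  # pmol min^-1 m^-2 mM^-1
    rate_sensitivity: float  # pmol m^-2 mM^-1
    potentiation_ratio: float
    basal_secretion: float  # pmol min^-1 m^-2
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.glucose_sensitivity <= 0 or self.potentiation_ratio <= 0:
            raise ValueError("glucose_sensitivity and potentiation_ratio must be > 0")
        if self.gms not in GMS_LEVELS:
            raise ValueError(f"unknown gms {self.gms!r}")


#: Class means for the secretion parameters (glucose sensitivity declines
#: along the NGM -> prediabetes -> T2D spectrum; overall levels sit near the
#: cohort means of the emulated study).
_GS_MEAN = {"NGM": 100.0, "prediabetes": 80.0, "T2D": 45.0}
_RS_MEAN = {"NGM": 800.0, "prediabetes": 750.0, "T2D": 500.0}


def draw_subject_truths(n: int, seed: int = 0) -> list[SubjectTruth]:
    """Draw latent scores, secretion truth and covariates for n subjects."""
    cov = draw_covariates(n, seed=seed)
    truths = []
    for k in range(n):
        rng = subject_rng(seed, k)
        gms = str(cov["gms"].iloc[k])
        latent = float(rng.standard_normal())
        gs = _GS_MEAN[gms] * np.exp(rng.normal(0.0, 0.35) + 0.10 * latent)
        rs = _RS_MEAN[gms] * np.exp(rng.normal(0.0, 0.5) + 0.10 * latent)
        pot = 1.6 * np.exp(rng.normal(0.0, 0.25))
        basal = 70.0 * np.exp(rng.normal(0.0, 0.20))
        truths.append(
            SubjectTruth(
                subject_id=f"S{k:05d}",
                latent_autonomic=latent,
                gms=gms,
                glucose_sensitivity=float(gs),
                rate_sensitivity=float(rs),
                potentiation_ratio=float(pot),
                basal_secretion=float(basal),
                covariates=cov.iloc[k].to_dict(),
            )
        )
    return truths


@dataclass(frozen=True)
class ModulationSpec:
    """RR-interval modulation amplitudes (ms) and noise for beat synthesis.

    Amplitudes are baseline values at latent score 0; every amplitude and
    the broadband jitter SD are multiplied by ``1 + amplitude_slope *
    latent`` (floored at 0.3), so a higher latent autonomic score yields
    uniformly larger variability in every band.
    """

    circadian_ms: float = 100.0
    lf_ms: float = 35.0
    hf_ms: float = 50.0
    lf_hz: float = 0.1
    hf_hz: float = 0.25
    jitter_ms: float = 12.0
    amplitude_slope: float = 0.2
    ectopic_fraction: float = 0.02
    artifact_fraction: float = 0.005

    def scale(self, latent: float) -> float:
        return max(1.0 + self.amplitude_slope * latent, 0.3)


def synthesize_beat_series(
    latent_autonomic: float = 0.0,
    duration_h: float = 24.0,
    mean_rr_ms: float = 850.0,
    modulation: ModulationSpec | None = None,
    seed: int = 0,
    subject_id: str = "",
    method: str = "integral",
) -> BeatSeries:
    """Synthesise a labelled 24-h beat series with banded RR modulation.

    The instantaneous RR interval is the mean plus circadian (24-h period),
    LF-band and HF-band sinusoids and broadband jitter, all scaled by the
    latent autonomic score.  With ``method="integral"`` (default, fully
    vectorised) beat times are the level crossings of the integrated
    instantaneous rate; intra-interval averaging then attenuates band
    amplitudes slightly.  ``method="sampled"`` instead sets each interval to
    the instantaneous RR at its onset, preserving modulation amplitudes
    exactly in the realised interval series (used for spectral oracles).
    A configurable fraction of beats is labelled ectopic or artifact.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    if not (300.0 <= mean_rr_ms <= 2000.0):
        raise ValueError("mean_rr_ms must lie in [300, 2000]")
    mod = modulation or ModulationSpec()
    s = mod.scale(latent_autonomic)
    rng = np.random.default_rng(seed)

    dur_s = duration_h * 3600.0
    dt = 0.25
    t = np.arange(0.0, dur_s + dt, dt)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    rr = (
        mean_rr_ms
        + s * mod.circadian_ms * np.sin(2 * np.pi * t / 86400.0 + phases[0])
        + s * mod.lf_ms * np.sin(2 * np.pi * mod.lf_hz * t + phases[1])
        + s * mod.hf_ms * np.sin(2 * np.pi * mod.hf_hz * t + phases[2])
    )
    if mod.jitter_ms > 0:
        # band-limited jitter: white on a 1-s grid, linearly interpolated
        tj = np.arange(0.0, dur_s + 1.0, 1.0)
        rr = rr + np.interp(t, tj, s * mod.jitter_ms * rng.standard_normal(tj.size))
    rr = np.maximum(rr, 300.0)

    if method == "integral":
        rate = 1000.0 / rr  # beats per second
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)])
        n_beats = int(np.floor(cum[-1]))
        beat_times = np.interp(np.arange(n_beats + 1, dtype=float), cum, t)
    elif method == "sampled":
        times = [0.0]
        while times[-1] < dur_s:
            times.append(times[-1] + np.interp(times[-1], t, rr) / 1000.0)
        beat_times = np.array(times[:-1] if times[-1] > dur_s else times)
    else:
        raise ValueError(f"unknown synthesis method {method!r}")

    labels = np.full(beat_times.size, SINUS, dtype=object)
    u = rng.random(beat_times.size)
    labels[u < mod.ectopic_fraction] = ECTOPIC
    labels[(u >= mod.ectopic_fraction) & (u < mod.ectopic_fraction + mod.artifact_fraction)] = ARTIFACT
    return BeatSeries(beat_time_s=beat_times, label=labels, subject_id=subject_id)


def score_level_composites(latents, modulation: ModulationSpec | None = None) -> pd.DataFrame:
    """Generator-side score-level HRV composites for signal-mode subjects.

    The time-domain composite follows the subject's common amplitude scale
    factor (every time-domain index is first-order proportional to it); the
    frequency-domain composite follows its square (band powers are quadratic
    in amplitude).  Both are z-scored across the cohort.  These are the
    reference values the metric pipeline's computed composites are checked
    against in the signal/score consistency tests.
    """
    mod = modulation or ModulationSpec()
    s = np.array([mod.scale(float(l)) for l in np.asarray(latents, dtype=float)])

    def z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std(ddof=1)

    return pd.DataFrame({"hrv_time_score": z(s), "hrv_freq_score": z(s**2)})


def synthesize_ogtt(
    truth: SubjectTruth,
    noise_cv: float = 0.04,
    seed: int = 0,
) -> betacell.OGTTRecord:
    """Synthesise a 7-point OGTT record by forward-simulating the secretion model.

    The glucose path is the subject's class template; C-peptide is obtained
    from the dose-response / rate-sensitivity / potentiation model through
    two-compartment kinetics, then perturbed by multiplicative lognormal
    noise with coefficient of variation ``noise_cv`` (floored at a small
    positive value).  Plasma insulin is a class-specific fraction of
    C-peptide, highest in prediabetes.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    cov = truth.covariates
    kin = betacell.cpeptide_kinetics(
        age=float(cov.get("age", 60.0)),
        sex=str(cov.get("sex", "M")),
        bmi=float(cov.get("bmi", 26.0)),
        gms=truth.gms,
    )
    glucose = GLUCOSE_TEMPLATES[truth.gms].copy()
    cp = betacell.forward_simulate_ogtt(
        glucose,
        kin,
        basal_secretion=truth.basal_secretion,
        glucose_sensitivity=truth.glucose_sensitivity,
        rate_sensitivity=truth.rate_sensitivity,
        potentiation_ratio=truth.potentiation_ratio,
    )
    insulin = INSULIN_CP_RATIO[truth.gms] * cp
    if noise_cv > 0:
        sig = np.sqrt(np.log(1.0 + noise_cv**2))
        glucose = glucose * np.exp(rng.normal(-0.5 * sig**2, sig, glucose.size))
        cp = cp * np.exp(rng.normal(-0.5 * sig**2, sig, cp.size))
        insulin = insulin * np.exp(rng.normal(-0.5 * sig**2, sig, insulin.size))
    floor = 1e-3
    return betacell.OGTTRecord(
        glucose_mmol_l=np.maximum(glucose, floor),
        cpeptide_pmol_l=np.maximum(cp, floor),
        insulin_pmol_l=np.maximum(insulin, floor),
        subject_id=truth.subject_id,
    )
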