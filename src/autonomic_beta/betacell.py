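"""Beta-cell response to an oral glucose load, estimated from 7-point OGTT data.

Five per-subject indices are produced:

* **C-peptidogenic index** — (CP30 - CP0) / (G30 - G0), early secretion;
* **overall insulin secretion** — AUC of C-peptide over AUC of glucose;
* **glucose sensitivity** — average slope of the beta-cell dose-response
  (pmol min^-1 m^-2 mM^-1), from the secretion model fit;
* **rate sensitivity** — secretion proportional to the positive rate of
  glucose rise (pmol m^-2 mM^-1), from the model fit;
* **potentiation ratio** — excursion of the time-varying potentiation
  factor, value at 120 min over value at baseline.

The secretion model treats insulin secretion rate (ISR, per m^2 body
surface) as::

    ISR(t) = P(t) * max(f0 + s_g * (G(t) - G0), 0) + s_r * max(dG/dt, 0)

with a linear dose-response of slope ``s_g`` anchored at fasting glucose, a
rate-sensitivity term ``s_r`` acting on rising glucose only, and a smooth
multiplicative potentiation factor ``P`` on a coarse knot grid, constrained
to time-average 1 over the record for identifiability.  Plasma C-peptide
follows two-compartment kinetics with population rate constants, so the
model is fitted to the measured C-peptide curve by regularised least
squares (``BetaCellModel.fit``) and can be run forward to synthesise
curves (:func:`forward_simulate_ogtt`).

The module also provides the Matsuda whole-body insulin-sensitivity index
and the cohort-level beta-cell composite z-score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import expm

__all__ = [
    "OGTT_TIMES_MIN",
    "OGTTRecord",
    "CPeptideKinetics",
    "cpeptide_kinetics",
    "ogtt_eligibility",
    "cpeptidogenic_index",
    "auc_trapezoid",
    "overall_insulin_secretion",
    "matsuda_index",
    "forward_simulate_ogtt",
    "deconvolve_isr",
    "BetaCellModel",
    "BetaCellResults",
    "betacell_composite",
    "BETACELL_INDICES",
]

OGTT_TIMES_MIN = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0])

BETACELL_INDICES = (
    "cpeptidogenic_index",
    "overall_insulin_secretion",
    "glucose_sensitivity",
    "potentiation_ratio",
    "rate_sensitivity",
)

FORWARD_DT_MIN = 1.0  # forward-integration grid
POTENTIATION_KNOT_MIN = 20.0  # knot spacing of the potentiation factor


@dataclass(frozen=True)
class OGTTRecord:
    """Glucose / C-peptide / insulin curves at 0, 15, 30, 45, 60, 90, 120 min."""

    glucose_mmol_l: np.ndarray
    cpeptide_pmol_l: np.ndarray
    insulin_pmol_l: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name in ("glucose_mmol_l", "cpeptide_pmol_l", "insulin_pmol_l"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != OGTT_TIMES_MIN.shape:
                raise ValueError(f"{name} must have exactly {OGTT_TIMES_MIN.size} samples")
            if not np.all(v > 0):
                raise ValueError(f"{name} must be strictly positive")
            object.__setattr__(self, name, v)

    @property
    def t_min(self) -> np.ndarray:
        return OGTT_TIMES_MIN

    @property
    def fasting_glucose_mmol_l(self) -> float:
        return float(self.glucose_mmol_l[0])


@dataclass(frozen=True)
class CPeptideKinetics:
    """Two-compartment C-peptide kinetic constants (min^-1) and volume (L)."""

    k01: float
    k12: float
    k21: float
    v_d: float
    bsa_m2: float

    def __post_init__(self) -> None:
        for name in ("k01", "k12", "k21", "v_d", "bsa_m2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def cpeptide_kinetics(
    age: float,
    sex: str,
    bmi: float,
    gms: str,
    height_m: float | None = None,
) -> CPeptideKinetics:
    """Population two-compartment C-peptide kinetics (Van Cauter-type scheme).

    The plasma decay is a double exponential with fast half-life 4.95 min
    and a slow half-life of 29.2 min (lean, normal glucose metabolism),
    27.3 min (obese, BMI >= 30) or 32.5 min (type 2 diabetes); the fast
    fraction is 0.76.  The distribution volume scales with body surface
    area (Mosteller, with sex-specific default heights when height is not
    supplied).  Deterministic in its inputs.
    """
    if not (18.0 <= age <= 100.0):
        raise ValueError(f"age out of range: {age}")
    if not (12.0 <= bmi <= 60.0):
        raise ValueError(f"BMI out of range: {bmi}")
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if gms not in ("NGM", "prediabetes", "T2D"):
        raise ValueError(f"unknown glucose metabolism status: {gms!r}")

    if height_m is None:
        height_m = 1.77 if sex == "M" else 1.63
    weight_kg = bmi * height_m**2
    bsa = np.sqrt(height_m * 100.0 * weight_kg / 3600.0)  # Mosteller

    frac_fast = 0.76
    t_half_fast = 4.95
    if gms == "T2D":
        t_half_slow = 32.5
    elif bmi >= 30.0:
        t_half_slow = 27.3
    else:
        t_half_slow = 29.2
    a = np.log(2.0) / t_half_fast
    b = np.log(2.0) / t_half_slow
    k21 = frac_fast * b + (1.0 - frac_fast) * a
    k01 = a * b / k21
    k12 = a + b - k21 - k01
    v_d = 1.92 * bsa + 0.64  # litres, linear in body surface area
    return CPeptideKinetics(k01=k01, k12=k12, k21=k21, v_d=v_d, bsa_m2=float(bsa))


def ogtt_eligibility(insulin_use: bool, fasting_glucose_mmol_l: float) -> bool:
    """OGTT eligibility: excluded when using insulin or fasting glucose > 11.0 mmol/L."""
    return not insulin_use and fasting_glucose_mmol_l <= 11.0


def cpeptidogenic_index(ogtt: OGTTRecord) -> float:
    """(CP30 - CP0) / (G30 - G0); NaN (flagged missing) when G30 == G0."""
    dg = ogtt.glucose_mmol_l[2] - ogtt.glucose_mmol_l[0]
    dcp = ogtt.cpeptide_pmol_l[2] - ogtt.cpeptide_pmol_l[0]
    if dg == 0:
        return np.nan
    return float(dcp / dg)


def auc_trapezoid(t_min: Sequence[float], y: Sequence[float]) -> float:
    """Trapezoidal area under the curve over the sampled interval."""
    t = np.asarray(t_min, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("need >= 2 strictly increasing time points")
    return float(np.trapezoid(y, t))


def overall_insulin_secretion(ogtt: OGTTRecord) -> float:
    """CP_AUC / G_AUC over the 2-h OGTT (unitless index of overall response)."""
    return auc_trapezoid(ogtt.t_min, ogtt.cpeptide_pmol_l) / auc_trapezoid(
        ogtt.t_min, ogtt.glucose_mmol_l
    )


MGDL_PER_MMOL = 18.016  # glucose mmol/L -> mg/dL
PMOL_PER_MICROU = 6.0  # insulin pmol/L -> uU/mL is division by 6.0


def matsuda_index(ogtt: OGTTRecord) -> float:
    """Matsuda insulin-sensitivity index: 10000 / sqrt(G0 * I0 * Gmean * Imean).

    Glucose in mg/dL (mmol/L x 18.016), insulin in uU/mL (pmol/L / 6.0);
    means taken over all seven OGTT samples.
    """
    g = ogtt.glucose_mmol_l * MGDL_PER_MMOL
    ins = ogtt.insulin_pmol_l / PMOL_PER_MICROU
    term = g[0] * ins[0] * g.mean() * ins.mean()
    if term <= 0:
        return np.nan
    return float(1e4 / np.sqrt(term))


# ---------------------------------------------------------------------------
# two-compartment forward machinery
# ---------------------------------------------------------------------------


def _step_matrices(kin: CPeptideKinetics, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact exponential stepping for the linear two-compartment system.

    State q = (central, peripheral) C-peptide mass in pmol; secretion S
    (pmol/min) held constant within a step: q_{n+1} = E q_n + F S.
    """
    A = np.array(
        [[-(kin.k01 + kin.k12), kin.k21], [kin.k12, -kin.k21]]
    )
    E = expm(A * dt)
    F = np.linalg.solve(A, (E - np.eye(2)) @ np.array([1.0, 0.0]))
    return E, F


def _integrate_cpeptide(
    isr_per_m2: np.ndarray,
    kin: CPeptideKinetics,
    dt: float,
    steady_state_isr: float | None = None,
) -> np.ndarray:
    """Central-compartment C-peptide concentration (pmol/L) on the ISR grid.

    Starts from the steady state of ``steady_state_isr`` (defaults to the
    first ISR value); secretion is taken piecewise-constant at the midpoint
    of each step.
    """
    E, F = _step_matrices(kin, dt)
    s0 = isr_per_m2[0] if steady_state_isr is None else steady_state_isr
    q1 = s0 * kin.bsa_m2 / kin.k01
    q = np.array([q1, kin.k12 * q1 / kin.k21])
    out = np.empty(isr_per_m2.size)
    out[0] = q[0] / kin.v_d
    for i in range(isr_per_m2.size - 1):
        s_mid = 0.5 * (isr_per_m2[i] + isr_per_m2[i + 1]) * kin.bsa_m2
        q = E @ q + F * s_mid
        out[i + 1] = q[0] / kin.v_d
    return out


def _dense_glucose(glucose_mmol_l: np.ndarray, t_obs: np.ndarray, dt: float):
    """Piecewise-linear glucose path and its derivative on the forward grid."""
    grid = np.arange(0.0, t_obs[-1] + 0.5 * dt, dt)
    g = np.interp(grid, t_obs, glucose_mmol_l)
    dg = np.gradient(g, grid)
    return grid, g, dg


def _potentiation_curve(knot_values: np.ndarray, knot_t: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of positive knots, normalised to time-average 1."""
    p = np.interp(grid, knot_t, knot_values)
    mean = np.trapezoid(p, grid) / (grid[-1] - grid[0])
    return p / mean


def _isr_curve(
    f0: float,
    s_g: float,
    s_r: float,
    p_grid: np.ndarray,
    g: np.ndarray,
    dg: np.ndarray,
    g_ref: float,
) -> np.ndarray:
    dose = np.maximum(f0 + s_g * (g - g_ref), 0.0)
    return p_grid * dose + s_r * np.maximum(dg, 0.0)


def forward_simulate_ogtt(
    glucose_mmol_l: np.ndarray,
    kinetics: CPeptideKinetics,
    basal_secretion: float,
    glucose_sensitivity: float,
    rate_sensitivity: float,
    potentiation_ratio: float = 1.0,
    t_obs: np.ndarray = OGTT_TIMES_MIN,
    dt: float = FORWARD_DT_MIN,
) -> np.ndarray:
    """Synthesise a C-peptide curve (pmol/L at ``t_obs``) from secretion truth.

    The glucose path is the piecewise-linear interpolant of the supplied
    samples; secretion follows the dose-response / rate / potentiation model
    anchored at fasting glucose, with the potentiation factor rising (or
    falling) linearly from baseline so that P(120)/P(0) equals
    ``potentiation_ratio``, time-normalised to mean 1.  Integration starts
    from the basal steady state.
    """
    if basal_secretion <= 0 or glucose_sensitivity < 0 or rate_sensitivity < 0:
        raise ValueError("secretion parameters out of range")
    if potentiation_ratio <= 0:
        raise ValueError("potentiation_ratio must be positive")
    t_obs = np.asarray(t_obs, dtype=float)
    grid, g, dg = _dense_glucose(np.asarray(glucose_mmol_l, float), t_obs, dt)
    raw = 1.0 + (potentiation_ratio - 1.0) * grid / grid[-1]
    p_grid = raw / (np.trapezoid(raw, grid) / (grid[-1] - grid[0]))
    isr = _isr_curve(
        basal_secretion / p_grid[0], glucose_sensitivity, rate_sensitivity,
        p_grid, g, dg, g_ref=g[0],
    )
    cp = _integrate_cpeptide(isr, kinetics, dt, steady_state_isr=basal_secretion)
    return np.interp(t_obs, grid, cp)


def deconvolve_isr(
    cpeptide_pmol_l: np.ndarray,
    kinetics: CPeptideKinetics,
    t_obs: np.ndarray = OGTT_TIMES_MIN,
    regularization: float = 5.0,
    bin_min: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Regularised non-negative deconvolution of the insulin secretion rate.

    ISR is piecewise-constant on ``bin_min``-minute bins; the fit minimises
    the squared C-peptide misfit plus ``regularization`` times the squared
    second difference of ISR, subject to ISR >= 0.  Integration starts from
    the steady state of the first bin's ISR, so a steady-state record yields
    a flat profile at clearance x concentration.

    Returns ``(bin_start_times_min, isr_pmol_min_m2)``.
    """
    if regularization < 0:
        raise ValueError("regularization must be >= 0")
    cp = np.asarray(cpeptide_pmol_l, dtype=float)
    t_obs = np.asarray(t_obs, dtype=float)
    edges = np.arange(0.0, t_obs[-1] + 0.5 * bin_min, bin_min)
    n_bins = edges.size - 1
    dt = FORWARD_DT_MIN
    grid = np.arange(0.0, t_obs[-1] + 0.5 * dt, dt)
    bin_of = np.minimum((grid // bin_min).astype(int), n_bins - 1)

    # response of the observed samples to each unit bin (init steady state
    # couples only to bin 0, keeping the map linear in the ISR vector)
    M = np.empty((t_obs.size, n_bins))
    for k in range(n_bins):
        isr = (bin_of == k).astype(float)
        cp_k = _integrate_cpeptide(
            isr, kinetics, dt, steady_state_isr=1.0 if k == 0 else 0.0
        )
        M[:, k] = np.interp(t_obs, grid, cp_k)

    D2 = np.zeros((max(n_bins - 2, 0), n_bins))
    for i in range(n_bins - 2):
        D2[i, i : i + 3] = (1.0, -2.0, 1.0)
    A = np.vstack([M, np.sqrt(regularization) * D2])
    b = np.concatenate([cp, np.zeros(D2.shape[0])])
    sol = optimize.lsq_linear(A, b, bounds=(0.0, np.inf))
    if not sol.success:
        raise RuntimeError(f"deconvolution failed: {sol.message}")
    return edges[:-1], sol.x


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class BetaCellModel:
    """Beta-cell secretion model for one subject's OGTT record.

    Parameters
    ----------
    ogtt : OGTTRecord
        Seven-point glucose / C-peptide / insulin record.
    kinetics : CPeptideKinetics
        Population two-compartment constants (see :func:`cpeptide_kinetics`).
    smoothness : float
        Penalty weight on the second difference of the log-potentiation
        knots (curvature of P on the 20-min knot grid).
    """

    def __init__(
        self,
        ogtt: OGTTRecord,
        kinetics: CPeptideKinetics,
        smoothness: float = 10.0,
        knot_min: float = POTENTIATION_KNOT_MIN,
    ) -> None:
        self.ogtt = ogtt
        self.kinetics = kinetics
        self.smoothness = smoothness
        self.knot_t = np.arange(0.0, ogtt.t_min[-1] + 0.5 * knot_min, knot_min)
        self._grid, self._g, self._dg = _dense_glucose(
            ogtt.glucose_mmol_l, ogtt.t_min, FORWARD_DT_MIN
        )

    # basal secretion implied by steady state at the fasting sample
    @property
    def basal_secretion(self) -> float:
        kin = self.kinetics
        return float(self.ogtt.cpeptide_pmol_l[0] * kin.v_d * kin.k01 / kin.bsa_m2)

    def _predict_cp(self, x: np.ndarray) -> np.ndarray:
        f0, s_g, s_r = x[0], x[1], x[2]
        p = _potentiation_curve(np.exp(x[3:]), self.knot_t, self._grid)
        isr = _isr_curve(f0, s_g, s_r, p, self._g, self._dg, g_ref=self._g[0])
        cp = _integrate_cpeptide(
            isr, self.kinetics, FORWARD_DT_MIN, steady_state_isr=p[0] * f0
        )
        return np.interp(self.ogtt.t_min, self._grid, cp)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        scale = max(float(self.ogtt.cpeptide_pmol_l.mean()), 1.0)
        misfit = (self._predict_cp(x) - self.ogtt.cpeptide_pmol_l) / (0.02 * scale)
        u = x[3:]
        curvature = np.sqrt(self.smoothness) * np.diff(u, 2)
        ridge = 0.02 * u  # pins the flat overall-scale direction of P
        return np.concatenate([misfit, curvature, ridge])

    def fit(self) -> "BetaCellResults":
        """Regularised least-squares fit; returns a :class:`BetaCellResults`."""
        og = self.ogtt
        # deconvolution-informed starting values
        _, isr0 = deconvolve_isr(og.cpeptide_pmol_l, self.kinetics, og.t_min)
        g_bins = np.interp(
            np.arange(isr0.size) * 5.0 + 2.5, self._grid, self._g
        )
        dg_bins = np.interp(
            np.arange(isr0.size) * 5.0 + 2.5, self._grid, self._dg
        )
        X = np.column_stack(
            [np.ones_like(g_bins), g_bins - self._g[0], np.maximum(dg_bins, 0.0)]
        )
        coef, *_ = np.linalg.lstsq(X, isr0, rcond=None)
        f0 = max(coef[0], 0.1 * self.basal_secretion, 1e-3)
        s_g = max(coef[1], 1.0)
        s_r = max(coef[2], 0.0)
        x0 = np.concatenate([[f0, s_g, s_r], np.zeros(self.knot_t.size)])
        lb = np.concatenate([[1e-6, 0.0, 0.0], np.full(self.knot_t.size, -3.0)])
        ub = np.concatenate([[np.inf, np.inf, np.inf], np.full(self.knot_t.size, 3.0)])
        sol = optimize.least_squares(
            self._residuals, x0, bounds=(lb, ub), method="trf", xtol=1e-10, ftol=1e-10
        )
        if not sol.success:
            raise RuntimeError(f"beta-cell model fit did not converge: {sol.message}")
        return BetaCellResults(self, sol)


class BetaCellResults:
    """Fitted beta-cell secretion parameters for one subject.

    Attributes
    ----------
    glucose_sensitivity : float
        Average slope of the dose-response (pmol min^-1 m^-2 mM^-1).
    rate_sensitivity : float
        Coefficient on rising glucose (pmol m^-2 mM^-1).
    potentiation_ratio : float
        P(120 min) / P(0 min).
    """

    def __init__(self, model: BetaCellModel, sol) -> None:
        self.model = model
        self._sol = sol
        x = sol.x
        self.dose_response_intercept = float(x[0])
        self.glucose_sensitivity = float(x[1])
        self.rate_sensitivity = float(x[2])
        self.potentiation_knots = np.exp(x[3:])
        p = _potentiation_curve(self.potentiation_knots, model.knot_t, model._grid)
        self.potentiation_t = p
        self.potentiation_ratio = float(p[-1] / p[0])
        self.isr_t = _isr_curve(
            self.dose_response_intercept,
            self.glucose_sensitivity,
            self.rate_sensitivity,
            p,
            model._g,
            model._dg,
            g_ref=model._g[0],
        )
        self.fitted_cpeptide = model._predict_cp(x)
        resid = self.fitted_cpeptide - model.ogtt.cpeptide_pmol_l
        self.rmse_pmol_l = float(np.sqrt(np.mean(resid**2)))

    def summary(self) -> pd.DataFrame:
        """One-row parameter table for this subject."""
        return pd.DataFrame(
            {
                "glucose_sensitivity": [self.glucose_sensitivity],
                "rate_sensitivity": [self.rate_sensitivity],
                "potentiation_ratio": [self.potentiation_ratio],
                "dose_response_intercept": [self.dose_response_intercept],
                "rmse_pmol_l": [self.rmse_pmol_l],
            },
            index=[self.model.ogtt.subject_id or 0],
        )


def betacell_profile(
    ogtt: OGTTRecord,
    kinetics: CPeptideKinetics,
    smoothness: float = 10.0,
) -> dict:
    """All five beta-cell indices for one subject (model-based ones via fit)."""
    res = BetaCellModel(ogtt, kinetics, smoothness=smoothness).fit()
    return {
        "cpeptidogenic_index": cpeptidogenic_index(ogtt),
        "overall_insulin_secretion": overall_insulin_secretion(ogtt),
        "glucose_sensitivity": res.glucose_sensitivity,
        "potentiation_ratio": res.potentiation_ratio,
        "rate_sensitivity": res.rate_sensitivity,
        "matsuda_index": matsuda_index(ogtt),
    }


def betacell_composite(profiles: pd.DataFrame) -> pd.Series:
    """Re-standardised overall beta-cell response composite z-score.

    Each of the five indices is z-scored on the analysis sample, the five
    z-scores are averaged, and the average is re-standardised to mean 0 /
    SD 1 (sample SD).  Requires complete cases on all five indices.
    """
    if len(profiles) < 2:
        raise ValueError("composite needs at least two subjects")
    sub = profiles[list(BETACELL_INDICES)]
    if sub.isna().any().any():
        raise ValueError("composite requires complete cases on all five indices")
    z = []
    for col in BETACELL_INDICES:
        sd = sub[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"index {col} has zero variance across the cohort")
        z.append((sub[col] - sub[col].mean()) / sd)
    comp = sum(z) / len(z)
    return ((comp - comp.mean()) / comp.std(ddof=1)).rename("betacell_composite_z")
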