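"""Observer-score calibrated drug-effect ranking.

The vascular effect index (VEI) condenses three treated/control ratios —
pseudovessel volume rV, supply index rSI, and segments-per-network rSN —
into one scalar via a weighted power law,

    VEI = x1 * rV**y1 + x2 * rSI**y2 + x3 * rSN**y3,

calibrated against mean human observer scores (OS) of side-by-side 3D
renderings.  :class:`VEIModel` is a scikit-learn style estimator whose
``fit`` reproduces the two-stage calibration (ordinary least squares for
the weights with exponents fixed at 1, then bounded nonlinear least
squares over all six parameters).  The reference calibration shipped with
the package is x = (0.6, -0.11, 0.44), y = (0.65, 1.5, 1.5).

Compartment-level effect indices map a treated/control ratio r onto the
bounded antisymmetric scale b(r) = (r - 1)/(r + 1) in (-1, +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

#: Reference calibration of the index against human observer scores.
REFERENCE_WEIGHTS = (0.6, -0.11, 0.44)
REFERENCE_EXPONENTS = (0.65, 1.5, 1.5)

RATIO_NAMES = ("rV", "rSI", "rSN")
GRADES = (-1.0, -0.5, 0.0, 0.5, 1.0)


class DegenerateDesignError(ValueError):
    """The ratio table carries no information to identify the model."""


def _validate_ratios(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("ratios must be an (n, 3) array of (rV, rSI, rSN)")
    if not np.all(np.isfinite(X)) or np.any(X <= 0):
        raise ValueError("ratios must be finite and positive")
    return X


class VEIModel(RegressorMixin, BaseEstimator):
    """Weighted power-law VEI model with two-stage calibration.

    Parameters
    ----------
    weight_bounds, exponent_bounds
        Box bounds for the stage-2 refinement; exponents are kept in
        (0.1, 5) so the power terms stay well-conditioned.

    Attributes (after ``fit``)
    --------------------------
    weights_ : (3,) fitted x1..x3
    exponents_ : (3,) fitted y1..y3
    stage1_weights_ : (3,) ordinary-least-squares weights at exponents 1
    residual_rms_ : root-mean-square OS residual of the final model
    """

    def __init__(self, weight_bounds=(-10.0, 10.0), exponent_bounds=(0.1, 5.0)):
        self.weight_bounds = weight_bounds
        self.exponent_bounds = exponent_bounds

    # -- core model ---------------------------------------------------------
    @staticmethod
    def _evaluate(X, weights, exponents):
        return (np.asarray(weights) * X ** np.asarray(exponents)).sum(axis=1)

    def fit(self, X, y):
        """Calibrate weights and exponents against observer scores y."""
        X = _validate_ratios(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if len(y) < 6:
            raise DegenerateDesignError("need >= 6 groups for six free parameters")
        logX = np.log(X)
        if np.any(logX.std(axis=0) < 1e-12):
            raise DegenerateDesignError(
                "a ratio column is constant (e.g. all ratios 1): model not identifiable"
            )
        # stage 1: OLS with exponents fixed at 1
        w0, *_ = np.linalg.lstsq(X, y, rcond=None)
        self.stage1_weights_ = w0.copy()
        lo = np.r_[np.full(3, self.weight_bounds[0]), np.full(3, self.exponent_bounds[0])]
        hi = np.r_[np.full(3, self.weight_bounds[1]), np.full(3, self.exponent_bounds[1])]
        p0 = np.r_[np.clip(w0, lo[:3] + 1e-9, hi[:3] - 1e-9), np.ones(3)]

        def residual(p):
            return self._evaluate(X, p[:3], p[3:]) - y

        sol = optimize.least_squares(residual, p0, bounds=(lo, hi), method="trf")
        self.weights_ = sol.x[:3]
        self.exponents_ = sol.x[3:]
        self.residual_rms_ = float(np.sqrt(np.mean(sol.fun**2)))
        self.n_groups_ = len(y)
        return self

    def predict(self, X):
        """VEI for each row of (rV, rSI, rSN)."""
        X = _validate_ratios(X)
        return self._evaluate(X, self.weights_, self.exponents_)

    def set_reference(self):
        """Load the shipped reference calibration (no fitting)."""
        self.weights_ = np.array(REFERENCE_WEIGHTS)
        self.exponents_ = np.array(REFERENCE_EXPONENTS)
        self.stage1_weights_ = self.weights_.copy()
        self.residual_rms_ = np.nan
        return self

    def to_dict(self) -> dict:
        return {
            "weights": list(map(float, self.weights_)),
            "exponents": list(map(float, self.exponents_)),
        }


def reference_model() -> VEIModel:
    """The reference VEI calibration as a ready-to-predict model."""
    return VEIModel().set_reference()


def compute_vei(ratios, model: VEIModel | None = None) -> np.ndarray | float:
    """VEI of one (rV, rSI, rSN) triple or an (n, 3) array of them."""
    model = model if model is not None else reference_model()
    arr = np.asarray(ratios, dtype=float)
    out = model.predict(arr)
    return float(out[0]) if arr.ndim == 1 else out


def fit_vei_model(table: pd.DataFrame) -> VEIModel:
    """Fit the VEI calibration to a ratio table with an ``os`` column."""
    X = table[list(RATIO_NAMES)].to_numpy(dtype=float)
    y = table["os"].to_numpy(dtype=float)
    return VEIModel().fit(X, y)


# ---------------------------------------------------------------------------
# observer scores
# ---------------------------------------------------------------------------

def aggregate_observer_score(ratings: pd.DataFrame, scale: str = "one") -> dict:
    """Mean observer score for one treatment group.

    ``ratings`` needs columns observer, treated_id, control_id, grade.
    Grades are on the five-tier scale -1, -0.5, 0, +0.5, +1; with
    ``scale="two"`` a +/-2-step file is divided by 2 on import.  Returns the
    score plus per-observer means and the rating count for audit.
    """
    if len(ratings) == 0:
        raise ValueError("no ratings to aggregate")
    grades = ratings["grade"].to_numpy(dtype=float)
    if scale == "two":
        grades = grades / 2.0
    elif scale != "one":
        raise ValueError("scale must be 'one' or 'two'")
    bad = ~np.isin(np.round(grades * 2) / 2, GRADES) | (np.abs(grades * 2 - np.round(grades * 2)) > 1e-9)
    if bad.any():
        raise ValueError(f"grades outside the five-tier scale: {sorted(set(grades[bad]))}")
    if (ratings["treated_id"] == ratings["control_id"]).any():
        raise ValueError("treated and control VTS must differ")
    per_observer = (
        pd.Series(grades, index=ratings["observer"].to_numpy()).groupby(level=0).mean()
    )
    return {
        "os": float(grades.mean()),
        "n_ratings": int(len(grades)),
        "per_observer": per_observer.to_dict(),
    }


def correlate_os_parameters(
    os_values, parameters: pd.DataFrame, ci: float = 0.95
) -> pd.DataFrame:
    """Pearson correlation of OS against each parameter column.

    Exact two-tailed p from the t distribution and a Fisher-z confidence
    interval; zero-variance parameters are flagged with undefined r.
    """
    y = np.asarray(os_values, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need >= 3 groups for correlation")
    z_crit = stats.norm.ppf(0.5 + ci / 2.0)
    rows = []
    for col in parameters.columns:
        x = parameters[col].to_numpy(dtype=float)
        if np.std(x) < 1e-300 or np.std(y) < 1e-300:
            rows.append(
                {"parameter": col, "r": np.nan, "p": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "undefined": True}
            )
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
        if abs(r) == 1.0:
            lo, hi_ = r, r
        else:
            z = np.arctanh(r)
            se = 1.0 / np.sqrt(n - 3)
            lo, hi_ = np.tanh(z - z_crit * se), np.tanh(z + z_crit * se)
        rows.append(
            {"parameter": col, "r": r, "p": p,
             "ci_low": float(lo), "ci_high": float(hi_), "undefined": False}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# compartment effect indices
# ---------------------------------------------------------------------------

def bounded_change(ratio) -> np.ndarray | float:
    """Antisymmetric bounded map b(r) = (r - 1)/(r + 1) of a positive ratio.

    b(1) = 0, b(r) -> +1 as r -> inf, b(r) -> -1 as r -> 0, and
    b(1/r) = -b(r).
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise ValueError("ratios must be finite and positive")
    out = (r - 1.0) / (r + 1.0)
    return float(out) if out.ndim == 0 else out


def effect_indices(treated_means: dict, control_means: dict) -> dict:
    """Compartment effect indices in [-1, +1] from descriptor group means.

    anti_angiogenic = -b(rel CD31 volume ratio): positive when vessels recede.
    vascular_disruptive = -b(total PV length ratio): positive when networks
    fragment.  tumor_cell / fibroblast = mean of b(density ratio) and
    b(relative-volume ratio): positive when the compartment expands.
    """
    def ratio(key):
        c = control_means.get(key)
        t = treated_means.get(key)
        if c is None or t is None:
            return None
        if not np.isfinite(c) or c <= 0:
            raise ValueError(f"control mean for {key!r} must be positive")
        return t / c

    out = {}
    r = ratio("rel_volume_cd31")
    if r is not None:
        out["anti_angiogenic"] = -bounded_change(r)
    r = ratio("pv_total_length_um")
    if r is not None:
        out["vascular_disruptive"] = -bounded_change(r)
    for role, name in (("tumor", "tumor_cell"), ("fibroblast", "fibroblast")):
        rd = ratio(f"{role}_cell_density_per_mm3")
        rv = ratio(f"rel_volume_{role}")
        parts = [bounded_change(x) for x in (rd, rv) if x is not None]
        if parts:
            out[name] = float(np.mean(parts))
    return out


@dataclass
class TreatmentSummary:
    """Per-group ratios, observer score, VEI and compartment indices."""

    group: str
    rV: float
    rSI: float
    rSN: float
    os: float = np.nan
    vei: float = np.nan
    indices: dict = None

    def __post_init__(self):
        for name in ("rV", "rSI", "rSN"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")
        if self.indices is None:
            self.indices = {}


def summarize_treatment(
    group: str,
    treated: pd.DataFrame,
    control: pd.DataFrame,
    model: VEIModel | None = None,
    os: float = np.nan,
) -> TreatmentSummary:
    """Build a treatment summary from treated and control descriptor rows.

    Ratios are treated-group means over control-group means of the relevant
    descriptor parameters (rV from the absolute CD31 volume, rSI from the
    supply index, rSN from segments per network).
    """
    def mean_of(df, col):
        return float(df[col].astype(float).mean())

    pairs = {
        "rV": "abs_volume_cd31_um3",
        "rSI": "pv_supply_index",
        "rSN": "pv_segments_per_network",
    }
    ratios = {}
    for name, col in pairs.items():
        c = mean_of(control, col)
        if not np.isfinite(c) or c <= 0:
            raise ValueError(f"control mean of {col} must be positive")
        ratios[name] = mean_of(treated, col) / c
    treated_means = treated.mean(numeric_only=True).to_dict()
    control_means = control.mean(numeric_only=True).to_dict()
    summary = TreatmentSummary(group=group, os=os, **ratios)
    summary.vei = compute_vei(
        np.array([ratios["rV"], ratios["rSI"], ratios["rSN"]]), model
    )
    summary.indices = effect_indices(treated_means, control_means)
    return summary
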