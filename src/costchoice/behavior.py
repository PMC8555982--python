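"""Logistic choice model with action cost, hysteresis, and spatial biases.

The probability of choosing juice B on a trial is modeled as

    P(choice B) = 1 / (1 + exp(-X))
    X = a0*qB - a1*qA + a2*(dB,+ - dA,+) + a3*(dn-1,B - dn-1,A)
        + a4*(dcostB=prev - dcostA=prev) + a5*(dofferB,L - dofferA,L)
        + a6*(dtargetB,L - dtargetA,L)

where the delta terms are 0/1 indicators: juice J offered at low cost;
juice J chosen and received on the previous trial; cost of J equal to the
previously chosen cost; offer of J on the left; target of J in the left
hemifield. Normalizing by the steepness a0 expresses every effect as a value
in units of juice B:

    rho = a1/a0   relative value of juice A
    xi  = a2/a0   action cost (value bonus of the short saccade)
    eta = a3/a0   choice hysteresis (juice)
    phi = a4/a0   cost hysteresis
    delta = a5/a0 offer-side bias
    eps = a6/a0   target-side bias

Sessions are fitted independently by unpenalized maximum likelihood. The
log-likelihood of a logistic model is concave, but near-deterministic
sessions can push coefficients to infinity (complete separation); estimates
are therefore bounded at +/-50 and a fit that lands on that bound is flagged
as non-converged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .task import HIGH, LOW, add_indicators

COEF_BOUND = 50.0
#: Fixed multi-start initializations (a0..a6).
_STARTS = (
    np.array([0.5, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0]),
    np.array([2.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0]),
    np.array([1.0, 0.5, 0.5, 0.1, 0.0, 0.0, 0.0]),
)

PARAM_NAMES = ("rho", "xi", "eta", "phi", "delta", "epsilon")


@dataclass
class BehaviorFit:
    """Maximum-likelihood coefficients of the choice model for one session."""

    session_id: str
    a: np.ndarray  # a0..a6
    loglik: float
    converged: bool
    n_trials: int

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, float)
        if self.a.shape != (7,):
            raise ValueError("expected 7 coefficients a0..a6")

    @property
    def a0(self) -> float:
        return float(self.a[0])

    @property
    def rho(self) -> float:
        return float(self.a[1] / self.a[0])

    @property
    def xi(self) -> float:
        return float(self.a[2] / self.a[0])

    @property
    def eta(self) -> float:
        return float(self.a[3] / self.a[0])

    @property
    def phi(self) -> float:
        return float(self.a[4] / self.a[0])

    @property
    def delta(self) -> float:
        return float(self.a[5] / self.a[0])

    @property
    def epsilon(self) -> float:
        return float(self.a[6] / self.a[0])

    def to_row(self) -> dict:
        row = {"session_id": self.session_id}
        row.update({f"a{i}": self.a[i] for i in range(7)})
        row.update({name: getattr(self, name) for name in PARAM_NAMES})
        row.update({"loglik": self.loglik, "converged": self.converged, "n_trials": self.n_trials})
        return row


def design_matrix(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Regressor matrix Z (columns matching a0..a6) and response y = chose B.

    The model is linear in the coefficients once qA enters with a negative
    sign: X = Z @ a.
    """
    df = trials if "d_cost" in trials.columns else add_indicators(trials)
    Z = np.column_stack(
        [
            df["qB"].to_numpy(float),
            -df["qA"].to_numpy(float),
            df["d_cost"].to_numpy(float),
            df["d_hyst"].to_numpy(float),
            df["d_costhyst"].to_numpy(float),
            df["d_offer"].to_numpy(float),
            df["d_target"].to_numpy(float),
        ]
    )
    y = (df["chosen_juice"] == "B").to_numpy(float)
    return Z, y


def choice_probability(a: np.ndarray, trial_or_trials) -> np.ndarray | float:
    """P(choice B) under coefficients ``a`` for one trial row or a trial table."""
    a = np.asarray(a, float)
    single = isinstance(trial_or_trials, pd.Series)
    df = trial_or_trials.to_frame().T if single else trial_or_trials
    Z, _ = design_matrix(df)
    p = _sigmoid(Z @ a)
    return float(p[0]) if single else p


def log_likelihood(a: np.ndarray, Z: np.ndarray, y: np.ndarray) -> float:
    x = Z @ np.asarray(a, float)
    # log P = y*x - log(1+e^x), computed stably
    return float(np.sum(y * x - np.logaddexp(0.0, x)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _fit_ml(Z: np.ndarray, y: np.ndarray, free: np.ndarray | None = None):
    """Bounded quasi-Newton ML fit; returns (coefficients, loglik, converged).

    ``free`` masks which of the 7 coefficients are estimated (others pinned
    at 0) — used for the simplified model behind the per-condition sigmoids.
    """
    if free is None:
        free = np.ones(7, bool)
    k = int(free.sum())
    Zf = Z[:, free]

    def nll(b):
        x = Zf @ b
        return float(np.sum(np.logaddexp(0.0, x) - y * x))

    def grad(b):
        p = _sigmoid(Zf @ b)
        return Zf.T @ (p - y)

    lb = np.full(k, -COEF_BOUND)
    # a0 > 0: steepness must be positive for the normalized parameters
    lb[0] = 1e-8
    bounds = list(zip(lb, np.full(k, COEF_BOUND)))
    best = None
    for start in _STARTS:
        res = minimize(nll, start[free], jac=grad, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    b = best.x
    a = np.zeros(7)
    a[free] = b
    hit_bound = bool(np.any(np.abs(b) >= COEF_BOUND - 1e-6))
    converged = bool(best.success) and not hit_bound
    if hit_bound:
        warnings.warn(
            "coefficient bound reached (likely complete separation); "
            "estimates capped at +/-50",
            stacklevel=3,
        )
    return a, -float(best.fun), converged


def fit_session(trials: pd.DataFrame, session_id: str | None = None) -> BehaviorFit:
    """Fit the choice model to one session by maximum likelihood.

    Requires at least two distinct offer types and at least one choice of
    each juice; otherwise the relative value is not identified.
    """
    df = trials if "d_cost" in trials.columns else add_indicators(trials)
    if session_id is None:
        ids = df["session_id"].unique()
        if len(ids) != 1:
            raise ValueError("trials must come from a single session (or pass session_id)")
        session_id = str(ids[0])
    offer_types = df[["qA", "costA", "qB", "costB"]].drop_duplicates()
    if len(offer_types) < 2:
        raise ValueError("need >= 2 distinct offer types to fit the choice model")
    chosen = set(df["chosen_juice"].unique())
    if chosen != {"A", "B"}:
        raise ValueError("both juices must be chosen at least once in the session")
    Z, y = design_matrix(df)
    a, ll, converged = _fit_ml(Z, y)
    return BehaviorFit(session_id=session_id, a=a, loglik=ll, converged=converged, n_trials=len(df))


def fit_sessions(trials: pd.DataFrame) -> pd.DataFrame:
    """Fit every session in a multi-session trial table; one row per session."""
    rows = []
    for sid, sdf in trials.groupby("session_id", sort=True):
        rows.append(fit_session(sdf, session_id=str(sid)).to_row())
    return pd.DataFrame(rows)


@dataclass
class ConditionPattern:
    """Raw and fitted choice pattern for one action-cost condition."""

    condition: str  # "A_high_cost" or "A_low_cost"
    points: pd.DataFrame  # per offer type: qA, qB, n, pct_B
    coeffs: np.ndarray | None  # simplified-model a0..a2 (shared across conditions)
    indifference_ratio: float  # qB:qA ratio at 50% B choices (qA = 1 convention)


def split_choice_pattern(trials: pd.DataFrame) -> dict[str, ConditionPattern]:
    """Per-condition choice patterns (trials split by the action cost of A).

    A simplified model — the quantity and cost terms only, hysteresis and
    spatial terms removed — is refitted to the session; its coefficients
    draw one sigmoid per condition. The indifference point for each
    condition solves X = 0 at qA = 1: ratio = rho_s -/+ xi_s for A offered
    at high/low cost respectively.
    """
    df = trials if "d_cost" in trials.columns else add_indicators(trials)
    Z, y = design_matrix(df)
    free = np.zeros(7, bool)
    free[:3] = True
    a_s, _, _ = _fit_ml(Z, y, free=free)
    rho_s, xi_s = a_s[1] / a_s[0], a_s[2] / a_s[0]

    out = {}
    for cond, mask in (
        ("A_high_cost", df["costA"] == HIGH),
        ("A_low_cost", df["costA"] == LOW),
    ):
        sub = df[mask]
        pts = (
            sub.groupby(["qA", "qB"], sort=True)
            .agg(n=("chosen_juice", "size"), pct_B=("chosen_juice", lambda s: 100.0 * (s == "B").mean()))
            .reset_index()
        )
        d_cost = 1 if cond == "A_high_cost" else -1  # value of (dB,+ - dA,+)
        if len(pts) >= 2:
            coeffs = a_s[:3].copy()
            indiff = rho_s - xi_s * d_cost
        else:
            coeffs, indiff = None, float("nan")
        out[cond] = ConditionPattern(cond, pts, coeffs, float(indiff))
    return out
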