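"""Per-subject logistic valuation models and trial-wise derived quantities.

A participant's accept/reject choices over mixed reward/shock offers are
modelled with logistic regression::

    SV = beta0 + beta_r * reward + beta_s * shock
    P(accept) = 1 / (1 + exp(-SV))

From the fitted model every trial gets a subjective value (SV), an accept
probability, a model-based confidence (SV**2, the quadratic extension of
value: high when SV unambiguously points to one choice, low near the
decision boundary), a signed value ``P(acc) - P(rej) = 2*P(acc) - 1`` in
(-1, 1), and one of four condition labels (confident/ambivalent x
accept/reject) from median splits of SV within each choice class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import InvalidArgumentError

CONDITIONS = ("AccCon", "AccAmb", "RejAmb", "RejCon")


@dataclass
class ValuationModel:
    """Fitted per-subject valuation model with diagnostics.

    When ``separation_flag`` is set the coefficients are unusable (the
    likelihood has no interior maximum); downstream code must check the
    flag rather than trusting silent estimates.
    """

    beta0: float
    beta_r: float
    beta_s: float
    se: tuple[float, float, float]
    loglik: float
    converged: bool
    separation_flag: bool

    @property
    def params(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_r, self.beta_s])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def fit_choice_model(trials: pd.DataFrame, separation_bound: float = 15.0,
                     tol: float = 1e-8, max_iter: int = 200) -> ValuationModel:
    """Maximum-likelihood logistic fit of choice ~ reward + shock.

    Fitting is by iteratively reweighted least squares with convergence
    tolerance ``tol`` on the deviance.  Quasi-complete separation is
    flagged when any coefficient magnitude exceeds ``separation_bound``
    (per percent-of-maximum unit) or the deviance collapses to zero; an
    input with only one choice class is flagged immediately.
    """
    if len(trials) < 20:
        raise InvalidArgumentError("need at least 20 trials to fit a valuation model")
    y = (trials["choice"].to_numpy() == "accept").astype(float)
    X = sm.add_constant(trials[["reward", "shock"]].to_numpy(), has_constant="add")
    if y.min() == y.max():
        return ValuationModel(np.nan, np.nan, np.nan, (np.nan,) * 3,
                              loglik=0.0, converged=False, separation_flag=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
            method="IRLS", tol=tol, maxiter=max_iter)
        params = np.asarray(res.params, dtype=float)
        separated = bool(np.max(np.abs(params)) > separation_bound
                         or res.deviance < 1e-6)
        se = (np.sqrt(np.diag(res.cov_params())) if not separated
              else np.full(3, np.nan))
        loglik = float(res.llf)
        converged = bool(res.converged) and not separated
    return ValuationModel(
        beta0=float(params[0]), beta_r=float(params[1]), beta_s=float(params[2]),
        se=tuple(float(s) for s in se), loglik=loglik,
        converged=converged, separation_flag=separated)


def subjective_value(model: ValuationModel, reward, shock):
    """SV = beta0 + beta_r * reward + beta_s * shock (exact linear form)."""
    if model.separation_flag:
        raise InvalidArgumentError("separated model: subjective values are undefined")
    return model.beta0 + model.beta_r * np.asarray(reward) + model.beta_s * np.asarray(shock)


def p_accept(sv):
    """Logistic accept probability, numerically stable for |sv| up to ~700."""
    return expit(np.asarray(sv, dtype=float))


def confidence(sv):
    """Model-based confidence: the quadratic extension of value, SV**2."""
    return np.square(np.asarray(sv, dtype=float))


def signed_value(p_acc):
    """P(accept) - P(reject) = 2 p - 1, normalizing value to (-1, 1)."""
    return 2.0 * np.asarray(p_acc, dtype=float) - 1.0


def categorize_trials(sv, choice, tie_rule: str = "alternate") -> np.ndarray:
    """Median-split condition labels within accepted and rejected trials.

    Accepts strictly above the accepted-trial SV median become AccCon and
    those strictly below AccAmb; rejects strictly above the rejected-trial
    median become RejAmb (closer to the boundary) and those below RejCon.
    Trials exactly at the median are assigned alternately, in trial order,
    to whichever bin is currently smaller (lower bin first on ties), which
    keeps the two bins of each choice class balanced to within one trial.
    """
    if tie_rule != "alternate":
        raise InvalidArgumentError(f"unknown tie rule {tie_rule!r}")
    sv = np.asarray(sv, dtype=float)
    choice = np.asarray(choice)
    labels = np.empty(sv.shape, dtype=object)

    for cls, upper, lower in (("accept", "AccCon", "AccAmb"),
                              ("reject", "RejAmb", "RejCon")):
        idx = np.flatnonzero(choice == cls)
        if idx.size < 2:
            if idx.size:
                warnings.warn(f"fewer than 2 {cls} trials; conditions for this "
                              "class are degenerate", stacklevel=2)
                labels[idx] = lower
            continue
        med = np.median(sv[idx])
        # strict sides are fixed; ties then fill whichever bin is behind,
        # alternating (lower first) when level -- guarantees |con - amb| <= 1
        n_upper = int((sv[idx] > med).sum())
        n_lower = int((sv[idx] < med).sum())
        prefer_lower = True
        for i in idx:
            if sv[i] > med:
                labels[i] = upper
            elif sv[i] < med:
                labels[i] = lower
            else:
                if n_lower < n_upper or (n_lower == n_upper and prefer_lower):
                    labels[i] = lower
                    n_lower += 1
                else:
                    labels[i] = upper
                    n_upper += 1
                prefer_lower = not prefer_lower
    return labels


def trial_estimates(model: ValuationModel, trials: pd.DataFrame) -> pd.DataFrame:
    """Attach model-based per-trial quantities to a trial table.

    Adds ``sv``, ``p_acc``, ``confidence``, ``signed_value`` and
    ``condition`` columns.  ``in_fmri`` is preserved if present, else set
    True.
    """
    out = trials.copy()
    sv = subjective_value(model, out["reward"].to_numpy(), out["shock"].to_numpy())
    out["sv"] = sv
    out["p_acc"] = p_accept(sv)
    out["confidence"] = confidence(sv)
    out["signed_value"] = signed_value(out["p_acc"].to_numpy())
    out["condition"] = categorize_trials(sv, out["choice"].to_numpy())
    if "in_fmri" not in out.columns:
        out["in_fmri"] = True
    return out


def write_trial_estimates_tsv(estimates: pd.DataFrame, path) -> None:
    estimates.to_csv(path, sep="\t", index=False, na_rep="n/a")
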