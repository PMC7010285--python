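"""Design matrices for event-related fMRI: parametric, categorical and FIR.

Builds the two GLMs of the analysis plus a finite-impulse-response (FIR)
variant, with gamma-HRF convolution on an oversampled grid, run-level
z-scoring of parametric modulators, orthogonalization of modulators
against their phase-baseline regressor (net effect: mean-centering),
Gaussian-weighted local-linear high-pass filtering, and collinearity
diagnostics (pairwise R^2 via Fisher-z averaging, variance inflation
factors).

GLM1 (parametric, 7 task columns)::

    Y = b_off X_off + b_com X_com + b_SVoff X_SVoff + b_SVcom X_SVcom
        + b_CDoff X_CDoff + b_CDcom X_CDcom + b_payout X_payout + e

GLM2 (categorical, 8 + 1 task columns): one column per condition
(AccCon/AccAmb/RejCon/RejAmb) and phase (offer/commit) plus the payout
nuisance.  The FIR design replaces HRF convolution with 18 time-lagged
indicator columns per regressor group, sampling the response every TR from
0 to (n_points - 1) * TR after onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError

GLM1_COLUMNS = ("offer", "commit", "sv_offer", "cd_offer",
                "sv_commit", "cd_commit", "payout")
GLM2_COLUMNS = ("AccCon_offer", "AccAmb_offer", "RejCon_offer", "RejAmb_offer",
                "AccCon_commit", "AccAmb_commit", "RejCon_commit", "RejAmb_commit",
                "payout")

#: portion of the payout alert that is explicitly modelled; the remainder
#: of the alert is left in baseline
PAYOUT_MODELLED_S = 4.550


# --------------------------------------------------------------------------
# HRF
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFSpec:
    """Gamma hemodynamic response function, parametrized by its peak.

    ``peak_delay_s`` is the time of the kernel maximum (the mode of the
    gamma density) and ``peak_dispersion_s`` its standard deviation.  The
    kernel is truncated at ``duration_s`` and normalized to unit peak.
    """

    peak_delay_s: float = 6.0
    peak_dispersion_s: float = 3.0
    duration_s: float = 32.0

    @property
    def shape_scale(self) -> tuple[float, float]:
        """(k, theta) of the gamma density with the requested mode and SD."""
        m, sd = self.peak_delay_s, self.peak_dispersion_s
        theta = (-m + np.sqrt(m * m + 4.0 * sd * sd)) / 2.0
        k = (sd / theta) ** 2
        return k, theta


def gamma_hrf(spec: HRFSpec, tr: float, oversample: int = 10) -> np.ndarray:
    """Unit-peak gamma kernel sampled at the scan grid.

    The density is evaluated on a ``tr / oversample`` grid, peak-normalized
    there, and decimated to scan resolution.
    """
    if tr <= 0:
        raise InvalidArgumentError("TR must be positive")
    kernel = _oversampled_hrf(spec.peak_delay_s, spec.peak_dispersion_s,
                              spec.duration_s, tr, oversample)
    return kernel[::oversample].copy()


@lru_cache(maxsize=32)
def _oversampled_hrf(peak, disp, duration, tr, oversample):
    dt = tr / oversample
    t = np.arange(0.0, duration, dt)
    k, theta = HRFSpec(peak, disp, duration).shape_scale
    kern = stats.gamma.pdf(t, a=k, scale=theta)
    peak_val = kern.max()
    if peak_val > 0:
        kern = kern / peak_val
    return kern


# --------------------------------------------------------------------------
# convolution and regressor arithmetic
# --------------------------------------------------------------------------

def convolve_events(onsets, durations, amplitudes, hrf: HRFSpec,
                    n_scans: int, tr: float, oversample: int = 10) -> np.ndarray:
    """Boxcar events convolved with the HRF, sampled at scan times.

    Boxcars are laid on a ``tr / oversample`` grid, convolved with the
    unit-peak kernel, scaled by the grid step (so values approximate the
    continuous convolution and are resolution-independent), and read out at
    frame starts.  Linear and homogeneous in the amplitudes.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    if not (len(onsets) == len(durations) == len(amplitudes)):
        raise InvalidArgumentError("onsets, durations, amplitudes must align")
    if np.any(durations < 0):
        raise InvalidArgumentError("durations must be non-negative")
    run_end = n_scans * tr
    if np.any(onsets < 0) or np.any(onsets > run_end):
        raise InvalidArgumentError("event onset outside the run")
    dt = tr / oversample
    n_fine = n_scans * oversample
    box = np.zeros(n_fine)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        box[i0:min(i1, n_fine)] += amp
    kern = _oversampled_hrf(hrf.peak_delay_s, hrf.peak_dispersion_s,
                            hrf.duration_s, tr, oversample)
    reg = np.convolve(box, kern)[:n_fine] * dt
    return reg[::oversample].copy()


def zscore_modulator(values) -> np.ndarray:
    """Standardize a parametric modulator to mean 0, population SD 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise InvalidArgumentError("modulator is constant or too short to z-score")
    return (v - v.mean()) / v.std()


def orthogonalize(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Residual of ``target`` after projection onto span{reference, constant}.

    The result is orthogonal to both the reference regressor and the
    constant; for a convolved modulator this amounts to mean-centering it
    relative to the phase baseline.
    """
    target = np.asarray(target, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if not np.any(reference):
        raise InvalidArgumentError("reference regressor is all zero")
    A = np.column_stack([np.ones_like(reference), reference])
    coef, *_ = np.linalg.lstsq(A, target, rcond=None)
    return target - A @ coef


# --------------------------------------------------------------------------
# design matrices
# --------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Named, time-resolved regressors for one run."""

    matrix: np.ndarray  # n_scans x n_regressors
    column_names: list[str]
    tr: float
    flagged_empty: set[str] = field(default_factory=set)

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.tr

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]

    def task_columns(self) -> list[str]:
        return [c for c in self.column_names if c != "const"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names,
                            index=self.frame_times)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _in_fmri(estimates: pd.DataFrame) -> pd.DataFrame:
    if "in_fmri" in estimates.columns:
        return estimates[estimates["in_fmri"].astype(bool)]
    return estimates


def _zscored_modulators(estimates: pd.DataFrame):
    """Run-level z-scored SV and confidence over trials entering the fMRI model."""
    est = _in_fmri(estimates)
    sv = zscore_modulator(est["sv"].to_numpy())
    cd = zscore_modulator(est["confidence"].to_numpy())
    return est, sv, cd


def build_glm1_design(estimates: pd.DataFrame, events: pd.DataFrame,
                      hrf: HRFSpec, n_scans: int, tr: float,
                      add_constant: bool = True) -> DesignMatrix:
    """The 7-column parametric design for one run.

    Offer/commit baselines are convolved boxcars over their phases; the SV
    and confidence modulators (z-scored within run) ride on the same
    boxcars and are orthogonalized, post-convolution, against their phase
    baseline plus a constant.  Payout alerts are modelled for their first
    4.55 s; runs without payout trials omit the column with a warning.
    """
    est, sv_z, cd_z = _zscored_modulators(estimates)
    keep_ids = set(est["offer_id"].astype(int))
    mods = pd.DataFrame({"offer_id": est["offer_id"].astype(int).to_numpy(),
                         "sv_z": sv_z, "cd_z": cd_z})

    def phase(trial_type):
        ev = events[events["trial_type"] == trial_type]
        ev = ev[ev["offer_id"].astype(int).isin(keep_ids)] if trial_type != "payout" else ev
        return ev.merge(mods, on="offer_id", how="left") if trial_type != "payout" else ev

    cols, names = [], []
    for ph in ("offer", "commit"):
        ev = phase(ph)
        if ev.empty:
            raise InvalidArgumentError(f"no {ph} events in run")
        base = convolve_events(ev["onset"], ev["duration"], np.ones(len(ev)),
                               hrf, n_scans, tr)
        sv_reg = convolve_events(ev["onset"], ev["duration"], ev["sv_z"],
                                 hrf, n_scans, tr)
        cd_reg = convolve_events(ev["onset"], ev["duration"], ev["cd_z"],
                                 hrf, n_scans, tr)
        cols += [base, orthogonalize(sv_reg, base), orthogonalize(cd_reg, base)]
        names += [ph, f"sv_{ph}", f"cd_{ph}"]
    pay = events[events["trial_type"] == "payout"]
    if len(pay):
        cols.append(convolve_events(pay["onset"],
                                    np.minimum(pay["duration"], PAYOUT_MODELLED_S),
                                    np.ones(len(pay)), hrf, n_scans, tr))
        names.append("payout")
    else:
        warnings.warn("run has no payout events; payout column omitted", stacklevel=2)
    order = [n for n in GLM1_COLUMNS if n in names]
    matrix = np.column_stack([cols[names.index(n)] for n in order])
    if add_constant:
        matrix = np.column_stack([matrix, np.ones(n_scans)])
        order = order + ["const"]
    dm = DesignMatrix(matrix=matrix, column_names=list(order), tr=tr)
    _flag_empty(dm)
    return dm


def build_glm2_design(estimates: pd.DataFrame, events: pd.DataFrame,
                      hrf: HRFSpec, n_scans: int, tr: float,
                      add_constant: bool = True) -> DesignMatrix:
    """The categorical design: 4 conditions x 2 phases + payout nuisance.

    Each condition column is the convolved boxcar of that condition's
    trials; a condition with no trials yields an all-zero column which is
    flagged so downstream contrasts involving it can be refused.
    """
    est = _in_fmri(estimates)
    if "condition" not in est.columns:
        raise InvalidArgumentError("estimates must carry condition labels")
    cond_of = dict(zip(est["offer_id"].astype(int), est["condition"]))
    cols, names = [], []
    for name in GLM2_COLUMNS[:-1]:
        cond, ph = name.rsplit("_", 1)
        ev = events[events["trial_type"] == ph]
        ev = ev[ev["offer_id"].astype(int).map(cond_of) == cond]
        if len(ev):
            cols.append(convolve_events(ev["onset"], ev["duration"],
                                        np.ones(len(ev)), hrf, n_scans, tr))
        else:
            cols.append(np.zeros(n_scans))
        names.append(name)
    pay = events[events["trial_type"] == "payout"]
    if len(pay):
        cols.append(convolve_events(pay["onset"],
                                    np.minimum(pay["duration"], PAYOUT_MODELLED_S),
                                    np.ones(len(pay)), hrf, n_scans, tr))
        names.append("payout")
    else:
        warnings.warn("run has no payout events; payout column omitted", stacklevel=2)
    matrix = np.column_stack(cols)
    if add_constant:
        matrix = np.column_stack([matrix, np.ones(n_scans)])
        names = names + ["const"]
    dm = DesignMatrix(matrix=matrix, column_names=list(names), tr=tr)
    _flag_empty(dm)
    return dm


def build_fir_design(estimates: pd.DataFrame, events: pd.DataFrame,
                     n_scans: int, tr: float, n_points: int = 18,
                     add_constant: bool = True) -> DesignMatrix:
    """Finite-impulse-response design sampling responses every TR.

    Four regressor groups -- categorical offer onset, parametric SV,
    parametric confidence (both z-scored within run), and payout alerts --
    each expand into ``n_points`` indicator columns; column ``k`` places
    the modulator amplitude at the scan nearest ``onset + k * TR``, so the
    last sampled time is ``(n_points - 1) * TR`` after onset (15.47 s for
    18 points at TR 0.91 s).  Overlapping windows from nearby trials sum,
    consistent with the linearity of the model.
    """
    if n_points < 1:
        raise InvalidArgumentError("n_points must be >= 1")
    est, sv_z, cd_z = _zscored_modulators(estimates)
    mods = dict(zip(est["offer_id"].astype(int),
                    zip(sv_z, cd_z)))
    offers = events[events["trial_type"] == "offer"]
    offers = offers[offers["offer_id"].astype(int).isin(mods)]
    pays = events[events["trial_type"] == "payout"]

    groups = [("offer", offers, np.ones(len(offers))),
              ("sv", offers, np.array([mods[i][0] for i in offers["offer_id"].astype(int)])),
              ("cd", offers, np.array([mods[i][1] for i in offers["offer_id"].astype(int)]))]
    if len(pays):
        groups.append(("payout", pays, np.ones(len(pays))))
    cols, names = [], []
    for gname, ev, amps in groups:
        onset_scan = np.rint(ev["onset"].to_numpy() / tr).astype(int)
        for k in range(n_points):
            col = np.zeros(n_scans)
            idx = onset_scan + k
            ok = idx < n_scans
            np.add.at(col, idx[ok], amps[ok])
            cols.append(col)
            names.append(f"{gname}_t{k:02d}")
    matrix = np.column_stack(cols)
    if add_constant:
        matrix = np.column_stack([matrix, np.ones(n_scans)])
        names = names + ["const"]
    dm = DesignMatrix(matrix=matrix, column_names=list(names), tr=tr)
    _flag_empty(dm)
    return dm


def _flag_empty(dm: DesignMatrix) -> None:
    for name in dm.task_columns():
        if not np.any(dm.column(name)):
            dm.flagged_empty.add(name)


# --------------------------------------------------------------------------
# high-pass filtering
# --------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _highpass_hat(n: int, sigma_s: float, tr: float) -> np.ndarray:
    """Hat matrix of a Gaussian-weighted local straight-line fit."""
    t = np.arange(n) * tr
    H = np.empty((n, n))
    for i in range(n):
        w = np.exp(-0.5 * ((t - t[i]) / sigma_s) ** 2)
        s0 = w.sum()
        s1 = (w * t).sum()
        s2 = (w * t * t).sum()
        det = s0 * s2 - s1 * s1
        H[i] = w * ((s2 - s1 * t[i]) + (s0 * t[i] - s1) * t) / det
    return H


def highpass_filter(series, sigma_s: float = 50.0, tr: float = 0.910):
    """FSL-style high-pass: subtract a Gaussian-weighted running line fit.

    At each time point a straight line is fitted to the series with
    Gaussian weights of SD ``sigma_s`` centred there; the fitted value is
    subtracted and the series mean added back.  Accepts a 1-D series or a
    2-D array of columns (n_scans x k); apply the same call to data and
    design so both live in the same filtered space.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    n = y.shape[0]
    if n < 3:
        raise InvalidArgumentError("series too short to filter")
    H = _highpass_hat(n, float(sigma_s), float(tr))
    out = y - H @ y + y.mean(axis=0, keepdims=True)
    return out[:, 0] if squeeze else out


def filter_design(dm: DesignMatrix, sigma_s: float = 50.0) -> DesignMatrix:
    """High-pass a design matrix column-wise (the constant is untouched)."""
    mat = highpass_filter(dm.matrix, sigma_s=sigma_s, tr=dm.tr)
    return DesignMatrix(matrix=mat, column_names=list(dm.column_names),
                        tr=dm.tr, flagged_empty=set(dm.flagged_empty))


# --------------------------------------------------------------------------
# collinearity diagnostics
# --------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    """Design-matrix collinearity summary across runs.

    ``pairwise_r2`` maps (column_a, column_b) to the Fisher-z-averaged
    squared correlation across runs; ``vif`` maps each column of interest
    to its median variance inflation factor 1 / (1 - R_i^2), where R_i^2
    comes from regressing the column on all remaining design columns.
    Rank-deficient cases are capped at ``vif_cap`` and flagged infinite.
    """

    pairwise_r2: dict
    vif: dict
    infinite_vif: set

    def to_json_dict(self) -> dict:
        return {
            "pairwise_r2": {f"{a}~{b}": v for (a, b), v in self.pairwise_r2.items()},
            "vif": dict(self.vif),
            "infinite_vif": sorted(self.infinite_vif),
        }


VIF_CAP = 1e6


def _vif_one(dm: DesignMatrix, name: str) -> float:
    yi = dm.column(name)
    others = [c for c in dm.column_names if c != name]
    X = dm.matrix[:, [dm.column_names.index(c) for c in others]]
    if "const" not in others:
        X = np.column_stack([X, np.ones(dm.n_scans)])
    beta, *_ = np.linalg.lstsq(X, yi, rcond=None)
    resid = yi - X @ beta
    ss_tot = np.sum((yi - yi.mean()) ** 2)
    if ss_tot == 0:
        raise InvalidArgumentError(f"column {name!r} is constant")
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    if r2 >= 1.0 - 1.0 / VIF_CAP:
        return np.inf
    return 1.0 / (1.0 - r2)


def collinearity_report(designs: list[DesignMatrix],
                        pairs: list[tuple[str, str]],
                        columns_of_interest: list[str]) -> CollinearityReport:
    """Pairwise R^2 (Fisher-z mean of |r| across runs, squared back) and
    median VIFs across a collection of run designs."""
    if not designs:
        raise InvalidArgumentError("need at least one design")
    pairwise = {}
    for a, b in pairs:
        zs = []
        for dm in designs:
            xa, xb = dm.column(a), dm.column(b)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                raise InvalidArgumentError(f"constant column in pair ({a}, {b})")
            r = float(np.corrcoef(xa, xb)[0, 1])
            r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
            zs.append(np.arctanh(r))
        pairwise[(a, b)] = float(np.tanh(np.mean(zs)) ** 2)
    vifs, infinite = {}, set()
    for name in columns_of_interest:
        per_run = [_vif_one(dm, name) for dm in designs]
        if np.any(np.isinf(per_run)):
            infinite.add(name)
            per_run = np.minimum(per_run, VIF_CAP)
        vifs[name] = float(np.median(per_run))
    return CollinearityReport(pairwise_r2=pairwise, vif=vifs, infinite_vif=infinite)
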