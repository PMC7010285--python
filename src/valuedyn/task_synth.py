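"""Synthetic two-phase approach-avoidance task: design, behavior, and BOLD.

This module generates fully synthetic datasets with known ground truth so
that every downstream analysis stage (choice modelling, GLM estimation,
permutation inference, ROI mixed models) can be validated by parameter
recovery.

The emulated experiment: on each trial an agent sees an offer pairing a
monetary reward with a painful shock (both expressed in percent-of-maximum
units, 0-100) and either accepts both or rejects both.  A trial has an
offer phase (4.55 s, deliberation only) followed by a commit phase
(2.73 s = 1.82 s response window + 0.91 s feedback).  A small number of
trials carry a 9.1 s payout alert.  Choices follow a logistic valuation
model, response times follow an inverse-quadratic function of signed value,
and BOLD volumes carry phase-specific value/confidence responses in
designated regions, embedded in AR(1) noise with slow drift.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import lfilter
from scipy.special import expit, logit

from .errors import InvalidArgumentError, NoSolutionError

#: scan repetition time of the emulated acquisition, seconds
DEFAULT_TR = 0.910

#: allowed fixation jitters, seconds (each an integer multiple of the TR)
FIXATION_CHOICES = (0.910, 1.820, 2.730)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialTiming:
    """Within-trial event durations in seconds.

    All durations are integer multiples of the TR so that event onsets fall
    exactly on scan times.  The commit phase spans the response window plus
    the feedback interval.
    """

    offer_s: float = 4.550
    response_s: float = 1.820
    feedback_s: float = 0.910
    payout_alert_s: float = 9.100
    tr_s: float = DEFAULT_TR

    @property
    def commit_s(self) -> float:
        return self.response_s + self.feedback_s

    def __post_init__(self):
        for name in ("offer_s", "response_s", "feedback_s", "payout_alert_s"):
            v = getattr(self, name)
            if v <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
            ratio = v / self.tr_s
            if abs(ratio - round(ratio)) > 1e-9:
                raise InvalidArgumentError(
                    f"{name}={v} is not an integer multiple of TR={self.tr_s}")


@dataclass(frozen=True)
class AgentSpec:
    """Ground-truth behavioral parameters for one simulated participant.

    ``beta0 + beta_r * reward + beta_s * shock`` is the subjective value
    (SV) of an offer; the accept probability is the logistic of SV.
    Response times are ``rt_b0 + rt_b1 * v + rt_b2 * v**2`` milliseconds
    plus Gaussian noise, where ``v = P(accept) - P(reject)`` is the signed
    value in [-1, 1]; ``rt_b2 < 0`` yields the inverse-quadratic slowing
    near the decision boundary.
    """

    beta0: float = 1.057
    beta_r: float = 0.199
    beta_s: float = -0.170
    rt_b0: float = 800.0
    rt_b1: float = -35.0
    rt_b2: float = -77.0
    rt_sigma: float = 150.0

    def sv(self, reward, shock):
        return self.beta0 + self.beta_r * np.asarray(reward) + self.beta_s * np.asarray(shock)


@dataclass
class SessionDesign:
    """A full session: offer grid, run assignment, payout flags and timing.

    ``trials`` is one row per trial with columns ``offer_id, run, trial,
    reward, shock, payout, fixation_s, onset_offer, onset_commit,
    onset_payout`` (onsets are seconds from run start; ``onset_payout`` is
    NaN on non-payout trials).
    """

    trials: pd.DataFrame
    n_runs: int
    timing: TrialTiming
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def trials_per_run(self) -> list[int]:
        return [int((self.trials["run"] == r).sum()) for r in range(self.n_runs)]

    def run_trials(self, run: int) -> pd.DataFrame:
        return self.trials[self.trials["run"] == run].reset_index(drop=True)

    def run_duration_s(self, run: int) -> float:
        """Seconds from run start to the offset of the last event."""
        t = self.run_trials(run)
        last = t.iloc[-1]
        end = last["onset_commit"] + self.timing.commit_s
        if last["payout"]:
            end = last["onset_payout"] + self.timing.payout_alert_s
        return float(end)


@dataclass
class BOLDSpec:
    """Generative specification for synthetic 4D BOLD runs.

    ``roi_masks`` maps region names to disjoint boolean 3D masks.
    ``effect_profiles`` maps region names to amplitude dictionaries whose
    keys are design-matrix column names (``offer``, ``commit``,
    ``sv_offer``, ``cd_offer``, ``sv_commit``, ``cd_commit``, ``payout``).
    A voxel's signal is the amplitude-weighted sum of the corresponding
    HRF-convolved regressors, i.e. the generative model is the exact twin
    of the parametric GLM used for estimation.  Noise is AR(1) with
    coefficient ``ar1_rho`` and innovation SD ``noise_sd``; drift is a
    linear ramp plus a slow sinusoid.
    """

    volume_shape: tuple[int, int, int] = (20, 20, 10)
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)
    effect_profiles: dict[str, dict[str, float]] = field(default_factory=dict)
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    drift_linear: float = 2.0
    drift_sin_amp: float = 1.0
    drift_sin_period_s: float = 120.0
    pad_s: float = 20.0

    def __post_init__(self):
        if not (0.0 <= self.ar1_rho < 1.0):
            raise InvalidArgumentError("ar1_rho must be in [0, 1)")
        occupancy = np.zeros(self.volume_shape, dtype=int)
        for name, mask in self.roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != tuple(self.volume_shape):
                raise InvalidArgumentError(
                    f"mask {name!r} shape {mask.shape} != volume {self.volume_shape}")
            self.roi_masks[name] = mask
            occupancy += mask
        if (occupancy > 1).any():
            raise InvalidArgumentError("roi masks must be disjoint")
        for name, prof in self.effect_profiles.items():
            for key, amp in prof.items():
                if not np.isfinite(amp):
                    raise InvalidArgumentError(f"amplitude {name}.{key} is not finite")


def default_bold_spec(volume_shape=(20, 20, 10), snr: float = 1.0,
                      noise_sd: float = 1.0, ar1_rho: float = 0.3) -> BOLDSpec:
    """The stock generative profile encoding the temporal dissociation.

    Three disjoint cubic regions are embedded in the volume:

    * ``vmpfc_like`` carries a value (SV) response during the offer phase
      and a confidence response during the commit phase -- and nothing else.
    * ``control_like`` (a dACC/lPFC stand-in) carries ambivalence, i.e.
      negative-confidence responses, in both phases.
    * ``null_like`` carries no task signal at all.

    ``snr`` scales the task amplitudes in units of the noise innovation SD.
    """
    nx, ny, nz = volume_shape
    if min(nx, ny) < 12 or nz < 5:
        raise InvalidArgumentError("volume too small for the three stock masks")

    def block(x0, x1, y0, y1, z0, z1):
        m = np.zeros(volume_shape, dtype=bool)
        m[x0:x1, y0:y1, z0:z1] = True
        return m

    cx, cy, cz = nx // 4, ny // 4, max(1, nz // 4)
    w = max(2, min(5, nx // 4))
    h = max(2, min(5, nz // 2))
    masks = {
        "vmpfc_like": block(cx - w // 2, cx - w // 2 + w, cy - w // 2, cy - w // 2 + w, cz, cz + h),
        "control_like": block(3 * cx - w // 2, 3 * cx - w // 2 + w,
                              3 * cy - w // 2, 3 * cy - w // 2 + w, cz, cz + h),
        "null_like": block(cx - w // 2, cx - w // 2 + w,
                           3 * cy - w // 2, 3 * cy - w // 2 + w, cz, cz + h),
    }
    a = snr * noise_sd
    profiles = {
        "vmpfc_like": {"offer": 0.5 * a, "commit": 0.5 * a,
                       "sv_offer": a, "cd_commit": a, "payout": 0.5 * a},
        "control_like": {"offer": 0.5 * a, "commit": 0.5 * a,
                         "cd_offer": -a, "cd_commit": -a},
        "null_like": {},
    }
    return BOLDSpec(volume_shape=tuple(volume_shape), roi_masks=masks,
                    effect_profiles=profiles, ar1_rho=ar1_rho, noise_sd=noise_sd)


# --------------------------------------------------------------------------
# session design
# --------------------------------------------------------------------------

def make_session_design(n_offers: int = 189, n_runs: int = 6,
                        payout_count: int = 10, seed: int = 0,
                        timing: TrialTiming | None = None) -> SessionDesign:
    """Lay out a session of mixed reward/shock offers split across runs.

    Offers sit on a near-uniform stratified grid over the [0, 100]^2
    reward x shock plane with small seeded jitter, so all four quadrants of
    the decision space are covered.  Presentation order is pseudo-random
    (seeded), run sizes differ by at most one trial, and ``payout_count``
    offers are flagged as payout trials without replacement.  Fixation
    jitter is drawn per trial from {0.91, 1.82, 2.73} s.
    """
    if n_offers <= 0 or n_runs <= 0 or payout_count < 0:
        raise InvalidArgumentError("counts must be positive (payout_count >= 0)")
    if n_offers < n_runs:
        raise InvalidArgumentError("need at least one offer per run")
    if payout_count > n_offers:
        raise InvalidArgumentError("payout_count exceeds n_offers")
    timing = timing or TrialTiming()
    rng = np.random.default_rng(seed)

    # stratified grid: g x g cell centres, drop surplus cells at random
    g = math.ceil(math.sqrt(n_offers))
    centres = (np.arange(g) + 0.5) * (100.0 / g)
    xx, yy = np.meshgrid(centres, centres, indexing="ij")
    cells = np.column_stack([xx.ravel(), yy.ravel()])
    keep = rng.choice(len(cells), size=n_offers, replace=False)
    pts = cells[np.sort(keep)]
    jitter = rng.uniform(-0.3, 0.3, size=pts.shape) * (100.0 / g)
    pts = np.clip(pts + jitter, 0.0, 100.0)

    order = rng.permutation(n_offers)
    reward = pts[order, 0]
    shock = pts[order, 1]
    payout = np.zeros(n_offers, dtype=bool)
    if payout_count:
        payout[rng.choice(n_offers, size=payout_count, replace=False)] = True

    # run sizes differ by <= 1; the remainder goes to the last runs, which
    # for 189 offers over 6 runs yields {31, 31, 31, 32, 32, 32}
    base, extra = divmod(n_offers, n_runs)
    sizes = [base + (1 if r >= n_runs - extra else 0) for r in range(n_runs)]
    run_idx = np.repeat(np.arange(n_runs), sizes)

    fixation = rng.choice(FIXATION_CHOICES, size=n_offers)

    rows = []
    pos = 0
    for r in range(n_runs):
        t_cursor = 0.0
        for k in range(sizes[r]):
            i = pos + k
            onset_offer = t_cursor + fixation[i]
            onset_commit = onset_offer + timing.offer_s
            onset_payout = onset_commit + timing.commit_s if payout[i] else np.nan
            t_cursor = onset_commit + timing.commit_s
            if payout[i]:
                t_cursor += timing.payout_alert_s
            rows.append((order[i], r, k, reward[i], shock[i], bool(payout[i]),
                         fixation[i], onset_offer, onset_commit, onset_payout))
        pos += sizes[r]
    trials = pd.DataFrame(rows, columns=[
        "offer_id", "run", "trial", "reward", "shock", "payout",
        "fixation_s", "onset_offer", "onset_commit", "onset_payout"])
    assert run_idx.shape == (n_offers,)
    return SessionDesign(trials=trials, n_runs=n_runs, timing=timing, seed=seed)


# --------------------------------------------------------------------------
# behavior
# --------------------------------------------------------------------------

def simulate_choices(agent: AgentSpec, session: SessionDesign,
                     seed: int = 0) -> pd.DataFrame:
    """Sample accept/reject choices from the agent's logistic valuation.

    Returns the session trial table augmented with ``sv_true``,
    ``p_acc_true``, ``choice`` ('accept'/'reject') and ``in_fmri`` (always
    True for simulated agents, which never miss the response deadline; the
    flag exists so real datasets with repeated missed-response offers can
    be handled downstream).
    """
    if not all(np.isfinite([agent.beta0, agent.beta_r, agent.beta_s])):
        raise InvalidArgumentError("agent coefficients must be finite")
    rng = np.random.default_rng(seed)
    out = session.trials.copy()
    sv = agent.sv(out["reward"].to_numpy(), out["shock"].to_numpy())
    p = expit(sv)
    accept = rng.random(len(out)) < p
    out["sv_true"] = sv
    out["p_acc_true"] = p
    out["choice"] = np.where(accept, "accept", "reject")
    out["in_fmri"] = True
    return out


def simulate_rts(agent: AgentSpec, signed_value, seed: int = 0,
                 floor_ms: float = 150.0) -> np.ndarray:
    """Response times (ms) as an inverse-quadratic function of signed value.

    RT = rt_b0 + rt_b1 * v + rt_b2 * v**2 + N(0, rt_sigma), truncated below
    at ``floor_ms``.
    """
    v = np.asarray(signed_value, dtype=float)
    if np.any(np.abs(v) > 1 + 1e-9):
        raise InvalidArgumentError("signed_value must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    rt = agent.rt_b0 + agent.rt_b1 * v + agent.rt_b2 * v ** 2
    if agent.rt_sigma > 0:
        rt = rt + rng.normal(0.0, agent.rt_sigma, size=v.shape)
    return np.maximum(rt, floor_ms)


def simulate_behavior(agent: AgentSpec, session: SessionDesign,
                      seed: int = 0) -> pd.DataFrame:
    """Choices plus RTs in one trial table (two independent seeded streams)."""
    ss = np.random.SeedSequence(seed).spawn(2)
    trials = simulate_choices(agent, session, seed=ss[0].generate_state(1)[0] % (2 ** 31))
    v = 2.0 * trials["p_acc_true"].to_numpy() - 1.0
    trials["rt_ms"] = simulate_rts(agent, v, seed=ss[1].generate_state(1)[0] % (2 ** 31))
    return trials


# --------------------------------------------------------------------------
# BOLD simulation
# --------------------------------------------------------------------------

def n_scans_for_run(session: SessionDesign, run: int, pad_s: float = 20.0) -> int:
    """Scans needed to cover the run plus padding for the delayed response."""
    return int(math.ceil((session.run_duration_s(run) + pad_s) / session.timing.tr_s))


def simulate_bold(session: SessionDesign, trial_estimates: pd.DataFrame,
                  spec: BOLDSpec, seed: int = 0,
                  subject_gain: float = 1.0) -> dict:
    """Synthesize 4D BOLD data for every run of a session.

    The task signal in each masked region is the amplitude-weighted sum of
    the parametric design-matrix columns (identical HRF and preprocessing
    conventions as the estimator), scaled by ``subject_gain``; drift and
    AR(1) noise are added everywhere.  Returns a dict with per-run 4D
    arrays (x, y, z, t), the design matrices used for generation, and scan
    counts.  Fully reproducible under ``seed``.
    """
    from .fmri_design import build_glm1_design, HRFSpec

    hrf = HRFSpec()
    tr = session.timing.tr_s
    rng = np.random.default_rng(seed)
    data, designs, n_scans_all = {}, {}, {}
    for run in range(session.n_runs):
        events = run_events(session, trial_estimates, run)
        n_scans = n_scans_for_run(session, run, spec.pad_s)
        design = build_glm1_design(trial_estimates[trial_estimates["run"] == run],
                                   events, hrf, n_scans, tr)
        vol = np.zeros(spec.volume_shape + (n_scans,), dtype=float)
        for name, mask in spec.roi_masks.items():
            profile = spec.effect_profiles.get(name, {})
            sig = np.zeros(n_scans)
            for col, amp in profile.items():
                if amp == 0.0:
                    continue
                if col not in design.column_names:
                    continue  # e.g. payout amplitude with no payout trials
                sig = sig + subject_gain * amp * design.column(col)
            vol[mask] += sig
        # drift + AR(1) noise over the whole volume
        t = np.arange(n_scans) * tr
        drift = (spec.drift_linear * (t / t[-1] - 0.5) if n_scans > 1 else 0.0)
        if spec.drift_sin_amp:
            drift = drift + spec.drift_sin_amp * np.sin(
                2 * np.pi * t / spec.drift_sin_period_s + rng.uniform(0, 2 * np.pi))
        vol += drift
        if spec.noise_sd > 0:
            nv = int(np.prod(spec.volume_shape))
            innov = rng.standard_normal((nv, n_scans), dtype=np.float32)
            innov *= spec.noise_sd
            noise = lfilter([1.0], [1.0, -spec.ar1_rho], innov, axis=1)
            vol += noise.reshape(spec.volume_shape + (n_scans,))
        data[run] = vol
        designs[run] = design
        n_scans_all[run] = n_scans
    return {"data": data, "designs": designs, "n_scans": n_scans_all}


def run_events(session: SessionDesign, trials: pd.DataFrame, run: int) -> pd.DataFrame:
    """Long-format (BIDS-style) event table for one run.

    One row per event with ``onset, duration, trial_type`` in
    {offer, commit, payout} plus trial attributes carried along.
    """
    t = trials[trials["run"] == run] if "run" in trials.columns else trials
    timing = session.timing
    rows = []
    for _, tr_row in t.iterrows():
        common = dict(offer_id=int(tr_row["offer_id"]), reward=tr_row["reward"],
                      shock=tr_row["shock"],
                      choice=tr_row.get("choice", ""),
                      rt_ms=tr_row.get("rt_ms", np.nan))
        rows.append(dict(onset=tr_row["onset_offer"], duration=timing.offer_s,
                         trial_type="offer", **common))
        rows.append(dict(onset=tr_row["onset_commit"], duration=timing.commit_s,
                         trial_type="commit", **common))
        if tr_row["payout"]:
            rows.append(dict(onset=tr_row["onset_payout"],
                             duration=timing.payout_alert_s,
                             trial_type="payout", **common))
    return pd.DataFrame(rows).sort_values("onset").reset_index(drop=True)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


# --------------------------------------------------------------------------
# agent cohorts
# --------------------------------------------------------------------------

#: group-level distribution of valuation coefficients used for synthetic
#: cohorts: truncated normals whose means and ranges mirror a typical
#: human approach-avoidance study population
COHORT_DISTRIBUTION = {
    "beta0": dict(mean=1.057, sd=2.5, lo=-6.420, hi=9.750),
    "beta_r": dict(mean=0.199, sd=0.10, lo=0.064, hi=0.547),
    "beta_s": dict(mean=-0.170, sd=0.10, lo=-0.547, hi=-0.050),
}


def sample_agents(n_subjects: int, seed: int = 0,
                  rt_b0: float = 800.0, rt_b1: float = -35.0,
                  rt_b2: float = -77.0, rt_sigma: float = 150.0) -> list[AgentSpec]:
    """Draw a cohort of preference-consistent agents (beta_r>0, beta_s<0)."""
    rng = np.random.default_rng(seed)

    def trunc(spec, size):
        out = np.empty(size)
        got = 0
        while got < size:
            draw = rng.normal(spec["mean"], spec["sd"], size=size)
            ok = draw[(draw >= spec["lo"]) & (draw <= spec["hi"])]
            take = min(size - got, len(ok))
            out[got:got + take] = ok[:take]
            got += take
        return out

    b0 = trunc(COHORT_DISTRIBUTION["beta0"], n_subjects)
    br = trunc(COHORT_DISTRIBUTION["beta_r"], n_subjects)
    bs = trunc(COHORT_DISTRIBUTION["beta_s"], n_subjects)
    return [AgentSpec(beta0=float(b0[i]), beta_r=float(br[i]), beta_s=float(bs[i]),
                      rt_b0=rt_b0, rt_b1=rt_b1, rt_b2=rt_b2, rt_sigma=rt_sigma)
            for i in range(n_subjects)]


# --------------------------------------------------------------------------
# pain calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PainCalibration:
    """Result of inverting a fitted stimulus-response sigmoid."""

    intensity: float
    extrapolated: bool
    params: tuple  # (lo, hi, x0, slope)


def calibrate_pain_sigmoid(intensities, ratings, target_rating: float = 8.0) -> PainCalibration:
    """Fit a 4-parameter logistic to shock-intensity/pain-rating pairs and
    return the intensity whose predicted rating equals ``target_rating``.

    The fitted curve is ``r(x) = lo + (hi - lo) / (1 + exp(-(x - x0)/s))``.
    Raises :class:`NoSolutionError` when the ratings are degenerate
    (constant) or the fitted curve never reaches the target.  The result is
    flagged ``extrapolated`` when the returned intensity falls outside the
    observed intensity range.
    """
    x = np.asarray(intensities, dtype=float)
    r = np.asarray(ratings, dtype=float)
    if x.size < 4 or x.size != r.size:
        raise InvalidArgumentError("need >= 4 (intensity, rating) pairs")
    if np.any((r < 0) | (r > 10)):
        raise InvalidArgumentError("ratings must lie in [0, 10]")
    if np.ptp(r) == 0:
        raise NoSolutionError("ratings are constant; no curve to invert")

    def f(x, lo, hi, x0, s):
        return lo + (hi - lo) * expit((x - x0) / s)

    span = np.ptp(x) or 1.0
    p0 = (float(r.min()), float(r.max()), float(np.median(x)), span / 4.0)
    try:
        params, _ = curve_fit(f, x, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise NoSolutionError(f"sigmoid fit failed: {exc}") from exc
    lo, hi, x0, s = params
    lo_a, hi_a = (lo, hi) if hi >= lo else (hi, lo)
    if not (lo_a < target_rating < hi_a):
        raise NoSolutionError(
            f"fitted curve spans [{lo_a:.3g}, {hi_a:.3g}]; never reaches {target_rating}")
    intensity = float(x0 + s * logit((target_rating - lo) / (hi - lo)))
    extrapolated = not (x.min() <= intensity <= x.max())
    return PainCalibration(intensity=intensity, extrapolated=extrapolated,
                           params=tuple(float(p) for p in params))


# --------------------------------------------------------------------------
# NIfTI / sidecar output
# --------------------------------------------------------------------------

def save_bold_nifti(volume4d: np.ndarray, path, tr_s: float = DEFAULT_TR) -> None:
    """Write a 4D volume as NIfTI-1 with the TR recorded in the header."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(volume4d, dtype=np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def save_mask_nifti(mask: np.ndarray, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine=np.eye(4))
    nib.save(img, str(path))


def ground_truth_sidecar(agent: AgentSpec, spec: BOLDSpec, path) -> None:
    """JSON sidecar recording the generative parameters of a dataset."""
    payload = {
        "agent": asdict(agent),
        "bold": {
            "volume_shape": list(spec.volume_shape),
            "effect_profiles": spec.effect_profiles,
            "ar1_rho": spec.ar1_rho,
            "noise_sd": spec.noise_sd,
            "drift_linear": spec.drift_linear,
            "drift_sin_amp": spec.drift_sin_amp,
            "drift_sin_period_s": spec.drift_sin_period_s,
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
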