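"""End-to-end synthetic-cohort experiment: one call from seeds to report.

``run_pipeline`` generates a cohort of agents performing the two-phase
approach-avoidance task, simulates their BOLD data with the stock
temporal-dissociation profile (value coding in the offer phase, confidence
coding in the commit phase, in a vmPFC-like region), then runs the full
analysis chain: per-subject choice models and trial estimates, run-level
parametric (GLM1) and categorical (GLM2) models, FIR time courses,
fixed-effects run combination, group sign-flip permutation tests with TFCE
inside the vmPFC-like mask, the offer/commit conjunction, the
linear-vs-quadratic ROI mixed-model comparison, the RT model, and design
collinearity diagnostics.  Everything is a deterministic function of the
configuration and its master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import choice_model as cm
from . import fmri_design as fd
from . import glm_estimation as ge
from . import roi_inference as ri
from . import task_synth as ts
from .errors import ConfigError, SeparationError

log = logging.getLogger("valuedyn")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable knobs of the synthetic experiment.

    The defaults mirror the emulated study: 28 subjects, 189 offers over
    six runs with 10 payout trials, TR 0.91 s.  ``n_perm`` defaults to the
    quick profile (1000); use 5000 for the full profile.  ``snr`` scales
    generative task amplitudes in units of the noise innovation SD, and
    ``subject_gain_sd`` adds between-subject variability in response gain.
    """

    n_subjects: int = 28
    n_offers: int = 189
    n_runs: int = 6
    payout_count: int = 10
    tr_s: float = 0.910
    volume_shape: tuple = (20, 20, 10)
    snr: float = 1.0
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    subject_gain_sd: float = 0.3
    n_perm: int = 1000
    alpha: float = 0.05
    whitening: str = "none"
    highpass_sigma_s: float = 50.0
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    fir_points: int = 18
    n_sim_ci: int = 5000
    rt_b0: float = 800.0
    rt_b1: float = -35.0
    rt_b2: float = -77.0
    rt_sigma: float = 150.0
    seed: int = 7

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        return d


_RANGES = {
    "n_subjects": (6, 1000), "n_offers": (8, 100000), "n_runs": (1, 100),
    "payout_count": (0, 100000), "tr_s": (1e-3, 60.0), "snr": (0.0, 1e6),
    "noise_sd": (0.0, 1e6), "ar1_rho": (0.0, 0.999), "subject_gain_sd": (0.0, 10.0),
    "n_perm": (100, 1_000_000), "alpha": (1e-6, 0.5), "highpass_sigma_s": (1.0, 1e4),
    "tfce_e": (0.0, 10.0), "tfce_h": (0.0, 10.0), "fir_points": (1, 100),
    "n_sim_ci": (100, 10_000_000), "rt_sigma": (0.0, 1e5),
}


def validate_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a dict or YAML/JSON file path.

    Unknown keys and out-of-range values are collected and reported
    together in a single :class:`ConfigError`.
    """
    if isinstance(source, PipelineConfig):
        raw = dataclasses.asdict(source)
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError([f"config file not found: {path}"])
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text) or {}
        else:
            raw = json.loads(text or "{}")
    problems = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            problems.append(f"unknown key: {key!r}")
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    if "volume_shape" in cfg_kwargs:
        vs = tuple(cfg_kwargs["volume_shape"])
        if len(vs) != 3 or any((not isinstance(x, (int, np.integer))) or x < 1 for x in vs):
            problems.append(f"volume_shape must be 3 positive integers, got {vs}")
        cfg_kwargs["volume_shape"] = vs
    for key, (lo, hi) in _RANGES.items():
        if key in cfg_kwargs:
            v = cfg_kwargs[key]
            if not isinstance(v, (int, float, np.integer, np.floating)) or not (lo <= v <= hi):
                problems.append(f"{key} must lie in [{lo}, {hi}], got {v!r}")
    if cfg_kwargs.get("whitening", "none") not in ("none", "ar1"):
        problems.append(f"whitening must be 'none' or 'ar1', got {cfg_kwargs['whitening']!r}")
    if not problems:
        try:
            cfg = PipelineConfig(**cfg_kwargs)
            if cfg.payout_count > cfg.n_offers:
                problems.append("payout_count exceeds n_offers")
            if cfg.n_offers < cfg.n_runs:
                problems.append("need at least one offer per run")
        except (TypeError, ValueError) as exc:
            problems.append(str(exc))
    if problems:
        raise ConfigError(problems)
    return cfg


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

GLM1_EFFECTS = ("sv_offer", "cd_offer", "sv_commit", "cd_commit")


def _derive_seed(seedseq: np.random.SeedSequence) -> int:
    return int(seedseq.generate_state(1)[0] % (2 ** 31))


@dataclass
class SubjectResult:
    """Everything the group level needs from one subject."""

    subject: int
    model: cm.ValuationModel
    estimates: pd.DataFrame
    effect_maps: dict          # GLM1 effect name -> 3-D effect map
    conj_maps: dict            # 'offer'/'commit' contrast -> 3-D effect map
    summaries: pd.DataFrame    # ROI condition summary rows
    fir_curves: dict           # 'sv'/'cd' -> per-TR coefficient curve
    glm1_designs: list = field(default_factory=list)


def process_subject(subject: int, agent: ts.AgentSpec, session: ts.SessionDesign,
                    bold_spec: ts.BOLDSpec, config: PipelineConfig,
                    seedseq: np.random.SeedSequence) -> SubjectResult:
    """Simulate one participant and run the within-subject analyses."""
    behav_ss, gain_ss, bold_ss = seedseq.spawn(3)
    trials = ts.simulate_behavior(agent, session, seed=_derive_seed(behav_ss))
    model = cm.fit_choice_model(trials)
    if model.separation_flag:
        raise SeparationError(f"subject {subject}: separated choice model")
    est = cm.trial_estimates(model, trials)
    est["subject"] = subject

    gain_rng = np.random.default_rng(_derive_seed(gain_ss))
    gain = float(max(0.1, gain_rng.normal(1.0, config.subject_gain_sd))) \
        if config.subject_gain_sd > 0 else 1.0
    sim = ts.simulate_bold(session, est, bold_spec, seed=_derive_seed(bold_ss),
                           subject_gain=gain)

    vmpfc = bold_spec.roi_masks["vmpfc_like"]
    hrf = fd.HRFSpec()
    tr = session.timing.tr_s
    eff_runs = {name: [] for name in GLM1_EFFECTS}
    conj_runs = {"offer": [], "commit": []}
    cond_runs = {name: [] for name in fd.GLM2_COLUMNS[:-1]}
    fir_sv, fir_cd = [], []
    glm1_designs = []
    for run in range(session.n_runs):
        vol = sim["data"][run]
        n_scans = sim["n_scans"][run]
        Y = vol.reshape(-1, n_scans).T
        Yf = fd.highpass_filter(Y, sigma_s=config.highpass_sigma_s, tr=tr)
        d1 = fd.filter_design(sim["designs"][run], sigma_s=config.highpass_sigma_s)
        glm1_designs.append(d1)
        g1 = ge.fit_run_glm(Yf, d1, whitening=config.whitening)
        for name in GLM1_EFFECTS:
            eff_runs[name].append(ge.contrast(g1, {name: 1.0}))

        run_est = est[est["run"] == run]
        events = ts.run_events(session, est, run)
        d2 = fd.filter_design(
            fd.build_glm2_design(run_est, events, hrf, n_scans, tr),
            sigma_s=config.highpass_sigma_s)
        g2 = ge.fit_run_glm(Yf, d2, whitening=config.whitening)
        for name in cond_runs:
            if name in g2.flagged_empty:
                continue
            cond_runs[name].append(ge.contrast(g2, {name: 1.0}))
        for phase, pos, neg in (("offer", "AccAmb_offer", "RejCon_offer"),
                                ("commit", "RejCon_commit", "AccAmb_commit")):
            if pos in g2.flagged_empty or neg in g2.flagged_empty:
                continue
            conj_runs[phase].append(ge.contrast(g2, {pos: 1.0, neg: -1.0}))

        # FIR on the ROI-mean series (the regional time course of interest)
        roi_series = Yf[:, vmpfc.ravel()].mean(axis=1)
        dF = fd.filter_design(
            fd.build_fir_design(run_est, events, n_scans, tr,
                                n_points=config.fir_points),
            sigma_s=config.highpass_sigma_s)
        gF = ge.fit_run_glm(roi_series[:, None], dF, whitening="none")
        coefs = dict(zip(gF.column_names, gF.betas[:, 0]))
        fir_sv.append([coefs[f"sv_t{k:02d}"] for k in range(config.fir_points)])
        fir_cd.append([coefs[f"cd_t{k:02d}"] for k in range(config.fir_points)])

    shape = bold_spec.volume_shape
    effect_maps = {name: ge.combine_runs(eff_runs[name]).effect.reshape(shape)
                   for name in GLM1_EFFECTS}
    conj_maps = {ph: ge.combine_runs(conj_runs[ph]).effect.reshape(shape)
                 for ph in conj_runs if conj_runs[ph]}
    phase_betas = {}
    for name, maps in cond_runs.items():
        if not maps:
            continue
        cond, phase = name.rsplit("_", 1)
        phase_betas[(phase, cond)] = ge.combine_runs(maps).effect.reshape(shape)
    summaries = ri.roi_condition_summaries(subject, phase_betas, vmpfc,
                                           est[est["in_fmri"]])
    fir_curves = {"sv": np.mean(fir_sv, axis=0), "cd": np.mean(fir_cd, axis=0)}
    return SubjectResult(subject=subject, model=model, estimates=est,
                         effect_maps=effect_maps, conj_maps=conj_maps,
                         summaries=summaries, fir_curves=fir_curves,
                         glm1_designs=glm1_designs)


def run_pipeline(config: PipelineConfig | dict | None = None,
                 out_dir=None) -> dict:
    """Run the whole synthetic experiment and return the report dict.

    When ``out_dir`` is given, the report, tidy tables, group statistical
    maps and masks are written there.  Identical config (including its
    master seed) yields a byte-identical report.
    """
    config = validate_config(config if config is not None else {})
    root = np.random.SeedSequence(config.seed)
    design_ss, agent_ss, subj_parent, perm_ss = root.spawn(4)

    session = ts.make_session_design(config.n_offers, config.n_runs,
                                     config.payout_count, _derive_seed(design_ss))
    agents = ts.sample_agents(config.n_subjects, _derive_seed(agent_ss),
                              rt_b0=config.rt_b0, rt_b1=config.rt_b1,
                              rt_b2=config.rt_b2, rt_sigma=config.rt_sigma)
    bold_spec = ts.default_bold_spec(config.volume_shape, snr=config.snr,
                                     noise_sd=config.noise_sd,
                                     ar1_rho=config.ar1_rho)
    vmpfc = bold_spec.roi_masks["vmpfc_like"]

    subj_ss = subj_parent.spawn(config.n_subjects)
    subjects = []
    n_separated = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(config.n_subjects):
            log.info("subject %d/%d", s + 1, config.n_subjects)
            try:
                subjects.append(process_subject(s, agents[s], session, bold_spec,
                                                config, subj_ss[s]))
            except SeparationError:
                # a quasi-separated valuation model has unusable magnitudes;
                # the subject is dropped from the imaging analyses, as such
                # participants would be in a real study
                log.warning("subject %d excluded: separated choice model", s)
                n_separated += 1
    if len(subjects) < 6:
        raise SeparationError("fewer than 6 usable subjects after exclusions")

    # --- choice-model summary --------------------------------------------
    fitted = np.array([[r.model.beta0, r.model.beta_r, r.model.beta_s]
                       for r in subjects])
    truth = np.array([[agents[r.subject].beta0, agents[r.subject].beta_r,
                       agents[r.subject].beta_s] for r in subjects])
    sign_ok = np.mean((fitted[:, 1] > 0) & (fitted[:, 2] < 0)) * 100.0
    choice_report = {
        "mean_beta0": float(fitted[:, 0].mean()),
        "mean_beta_r": float(fitted[:, 1].mean()),
        "mean_beta_s": float(fitted[:, 2].mean()),
        "sign_recovery_pct": float(sign_ok),
        "median_abs_err_beta_r": float(np.median(np.abs(fitted[:, 1] - truth[:, 1]))),
        "median_abs_err_beta_s": float(np.median(np.abs(fitted[:, 2] - truth[:, 2]))),
        "n_excluded_separation": int(n_separated),
        "n_subjects_used": len(subjects),
    }

    # --- group permutation tests inside the vmPFC-like mask --------------
    perm_children = perm_ss.spawn(len(GLM1_EFFECTS) + 2)
    group_effects = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, name in enumerate(GLM1_EFFECTS):
            maps = np.stack([r.effect_maps[name] for r in subjects])
            res = ge.group_permutation_test(
                maps, mask=vmpfc, n_perm=config.n_perm, enhancement="tfce",
                alternative="greater", seed=_derive_seed(perm_children[i]),
                E=config.tfce_e, H=config.tfce_h)
            group_effects[name] = {
                "sig_voxels": int(res.significant(config.alpha).sum()),
                "min_p": float(res.p_corr[res.mask].min()),
                "max_t": float(res.t_obs[res.mask].max()),
                "result": res,
            }

        # --- conjunction: value at offer AND confidence at commit --------
        conj_results = {}
        for j, ph in enumerate(("offer", "commit")):
            maps = np.stack([r.conj_maps[ph] for r in subjects if ph in r.conj_maps])
            conj_results[ph] = ge.group_permutation_test(
                maps, mask=vmpfc, n_perm=config.n_perm, enhancement="tfce",
                alternative="greater",
                seed=_derive_seed(perm_children[len(GLM1_EFFECTS) + j]),
                E=config.tfce_e, H=config.tfce_h)
    conj_mask = ge.conjunction(conj_results["offer"].significant(config.alpha),
                               conj_results["commit"].significant(config.alpha))
    conjunction_report = {
        "n_voxels": int(conj_mask.sum()),
        "contained_in_roi": bool(np.all(vmpfc[conj_mask])) if conj_mask.any() else True,
    }

    # --- ROI linear-vs-quadratic comparison ------------------------------
    summaries = pd.concat([r.summaries for r in subjects], ignore_index=True)
    # subjects missing any phase x condition cell (e.g. almost no rejects)
    # cannot enter the 4-condition mixed models; drop them with a count
    complete = (summaries.dropna(subset=["roi_mean", "signed_value_mean"])
                .groupby("subject")
                .apply(lambda d: d.groupby("phase")["condition"].nunique().eq(4).all(),
                       include_groups=False))
    keep = set(complete[complete].index)
    n_incomplete = summaries["subject"].nunique() - len(keep)
    summaries = summaries[summaries["subject"].isin(keep)]
    if len(keep) < 2:
        raise SeparationError("fewer than 2 subjects with complete condition sets")
    roi_comparison = {
        ph: ri.compare_linear_quadratic(summaries, ph, alpha=config.alpha,
                                        n_sim=config.n_sim_ci, seed=config.seed + k)
        for k, ph in enumerate(ri.PHASES)
    }

    # --- FIR time courses -------------------------------------------------
    times = np.arange(config.fir_points) * config.tr_s
    sv_curve = np.mean([r.fir_curves["sv"] for r in subjects], axis=0)
    cd_curve = np.mean([r.fir_curves["cd"] for r in subjects], axis=0)
    sv_peak = float(times[int(np.argmax(sv_curve))])
    cd_peak = float(times[int(np.argmax(cd_curve))])
    fir_report = {
        "times_s": times.tolist(),
        "sv_curve": [float(x) for x in sv_curve],
        "cd_curve": [float(x) for x in cd_curve],
        "sv_peak_s": sv_peak,
        "cd_peak_s": cd_peak,
        "sv_peaks_before_cd": bool(sv_peak < cd_peak),
    }

    # --- behavioral RT model ----------------------------------------------
    all_trials = pd.concat([r.estimates for r in subjects], ignore_index=True)
    rt_res = ri.rt_analysis(all_trials, n_sim=config.n_sim_ci, seed=config.seed + 17)
    rt_report = {
        "params": dict(zip(rt_res.model.param_names, map(float, rt_res.model.params))),
        "se": dict(zip(rt_res.model.param_names, map(float, rt_res.model.se))),
        "cis": {k: list(v) for k, v in rt_res.cis.items()},
        "random_intercept_sd": rt_res.model.sigma_u,
        "excluded_stage1": rt_res.exclusions.n_stage1,
        "excluded_stage2": rt_res.exclusions.n_stage2,
    }

    # --- collinearity ------------------------------------------------------
    all_designs = [d for r in subjects for d in r.glm1_designs]
    coll = fd.collinearity_report(
        all_designs,
        pairs=[("sv_offer", "cd_offer"), ("sv_commit", "cd_commit")],
        columns_of_interest=list(GLM1_EFFECTS))

    # --- acceptance-style checks ------------------------------------------
    checks = [
        _check("offer_winner_linear", "linear", roi_comparison["offer"].winner),
        _check("commit_winner_quadratic", "quadratic", roi_comparison["commit"].winner),
        _check("sv_offer_significant", True, group_effects["sv_offer"]["sig_voxels"] > 0),
        _check("cd_commit_significant", True, group_effects["cd_commit"]["sig_voxels"] > 0),
        _check("sv_commit_null", 0, group_effects["sv_commit"]["sig_voxels"]),
        _check("cd_offer_null", 0, group_effects["cd_offer"]["sig_voxels"]),
        _check("conjunction_nonempty_in_roi", True,
               conjunction_report["n_voxels"] > 0 and conjunction_report["contained_in_roi"]),
        _check("fir_sv_peaks_before_cd", True, fir_report["sv_peaks_before_cd"]),
        _check("rt_quadratic_negative", True,
               rt_report["params"]["signed_value_sq"] < 0),
    ]
    choice_report["n_incomplete_conditions"] = int(n_incomplete)
    report = {
        "config": config.to_json_dict(),
        "choice": choice_report,
        "collinearity": coll.to_json_dict(),
        "group_effects": {k: {kk: vv for kk, vv in v.items() if kk != "result"}
                          for k, v in group_effects.items()},
        "conjunction": conjunction_report,
        "roi_comparison": {ph: mc.to_json_dict() for ph, mc in roi_comparison.items()},
        "fir": fir_report,
        "rt": rt_report,
        "checks": checks,
        "overall_pass": bool(all(c["passed"] for c in checks)),
    }
    if out_dir is not None:
        _write_outputs(Path(out_dir), report, summaries, all_trials,
                       group_effects, conj_mask, bold_spec, config)
    return report


def _check(name, expected, observed):
    return {"name": name, "expected": expected, "observed": observed,
            "passed": bool(expected == observed if not isinstance(expected, bool)
                           else bool(observed) == expected)}


def _write_outputs(out, report, summaries, all_trials, group_effects,
                   conj_mask, bold_spec, config):
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    summaries.to_csv(out / "roi_condition_summaries.tsv", sep="\t", index=False)
    all_trials.to_csv(out / "trial_estimates.tsv", sep="\t", index=False, na_rep="n/a")
    for name, info in group_effects.items():
        res = info["result"]
        ts.save_bold_nifti(res.t_obs[..., None], out / f"group_t_{name}.nii.gz",
                           tr_s=config.tr_s)
        ts.save_bold_nifti(res.p_corr[..., None], out / f"group_pfwe_{name}.nii.gz",
                           tr_s=config.tr_s)
    ts.save_mask_nifti(conj_mask, out / "conjunction_mask.nii.gz")
    for name, mask in bold_spec.roi_masks.items():
        ts.save_mask_nifti(mask, out / f"mask_{name}.nii.gz")
    hrf = fd.HRFSpec()
    with open(out / "design_sidecar.json", "w") as fh:
        json.dump({
            "tr_s": config.tr_s,
            "hrf": {"family": "gamma", "peak_delay_s": hrf.peak_delay_s,
                    "peak_dispersion_s": hrf.peak_dispersion_s,
                    "duration_s": hrf.duration_s, "normalization": "unit peak"},
            "highpass_sigma_s": config.highpass_sigma_s,
            "processing_order": ["convolve", "orthogonalize", "highpass"],
            "modulator_zscore": "within-run, population SD",
        }, fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# synthetic dataset export (for the `synth` CLI subcommand)
# --------------------------------------------------------------------------

def export_synthetic_dataset(out_dir, n_subjects: int = 2, seed: int = 0,
                             snr: float = 1.0, volume_shape=(20, 20, 10),
                             n_offers: int = 189, n_runs: int = 6,
                             payout_count: int = 10) -> None:
    """Write a BIDS-flavored synthetic dataset to disk.

    Per subject: events TSV and 4D BOLD NIfTI per run, a ground-truth JSON
    sidecar; per dataset: the ROI masks.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    design_ss, agent_ss, subj_parent = root.spawn(3)
    session = ts.make_session_design(n_offers, n_runs, payout_count,
                                     _derive_seed(design_ss))
    agents = ts.sample_agents(n_subjects, _derive_seed(agent_ss))
    spec = ts.default_bold_spec(volume_shape, snr=snr)
    for name, mask in spec.roi_masks.items():
        ts.save_mask_nifti(mask, out / f"mask_{name}.nii.gz")
    for s, (agent, sub_ss) in enumerate(zip(agents, subj_parent.spawn(n_subjects))):
        sdir = out / f"sub-{s + 1:02d}"
        sdir.mkdir(exist_ok=True)
        b_ss, v_ss = sub_ss.spawn(2)
        trials = ts.simulate_behavior(agent, session, seed=_derive_seed(b_ss))
        model = cm.fit_choice_model(trials)
        if model.separation_flag:
            # fitted model unusable; fall back to the generating parameters
            # so the exported estimates stay well defined
            model = cm.ValuationModel(agent.beta0, agent.beta_r, agent.beta_s,
                                      (np.nan,) * 3, np.nan, True, False)
        est = cm.trial_estimates(model, trials)
        sim = ts.simulate_bold(session, est, spec, seed=_derive_seed(v_ss))
        for run in range(session.n_runs):
            ts.write_events_tsv(ts.run_events(session, est, run),
                                sdir / f"sub-{s + 1:02d}_run-{run + 1}_events.tsv")
            ts.save_bold_nifti(sim["data"][run],
                               sdir / f"sub-{s + 1:02d}_run-{run + 1}_bold.nii.gz",
                               tr_s=session.timing.tr_s)
        ts.ground_truth_sidecar(agent, spec, sdir / "ground_truth.json")
        cm.write_trial_estimates_tsv(est, sdir / "trial_estimates.tsv")
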