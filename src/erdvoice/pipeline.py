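"""End-to-end orchestration: simulate -> preprocess -> ERD -> acoustics ->
statistics, with seeded reproducibility and a recovery summary comparing
pipeline estimates against the simulator's ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acoustics, cohort, melody, preprocess, spectral, stats, synth
from .cohort import ErdGroundTruth, SimulationParams
from .montage import default_montage
from .spectral import (BASELINE_S, DEFAULT_BANDS, PERCEPTION_WINDOW_S,
                       PRODUCTION_WINDOW_S, TIMECOURSE_WINDOWS, RoiSpec)

log = logging.getLogger("erdvoice")


@dataclass
class RunConfig:
    """Everything a run depends on; fully serializable and hashable."""

    seed: int = 0
    n_participants: int = 19
    n_trials: int = 120
    coupling_rho: float = 0.49
    amp_uv: float = 100.0
    prob_sd: float = 5.0
    kurt_sd: float = 5.0
    highpass_hz: float = 1.0
    eog_channel: str = "Fpz"
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    humanness_window_s: tuple = (0.25, 3.0)
    artifacts: bool = True
    n_melodies_scored: int = 120
    feature_regression: bool = False   # per-stimulus descriptors are costly
    erd_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = {k: list(v) for k, v in d["bands"].items()}
        d["humanness_window_s"] = list(d["humanness_window_s"])
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        if "humanness_window_s" in d:
            d["humanness_window_s"] = tuple(d["humanness_window_s"])
        return cls(**d)


def _participant_erd(profile, schedule, erd_gt, config, seed):
    """One participant: simulate, preprocess, regional band-power tables."""
    from .montage import FRONTOCENTRAL_6

    raw = cohort.simulate_eeg(
        profile, schedule, erd=erd_gt, rng_seed=seed, artifacts=config.artifacts
    )
    percep, prod = preprocess.preprocess_pipeline(
        raw,
        eog_channel=config.eog_channel,
        cutoff_hz=config.highpass_hz,
        amp_uv=config.amp_uv,
        prob_sd=config.prob_sd,
        kurt_sd=config.kurt_sd,
    )
    roi = RoiSpec()
    windows = {
        "analysis": PERCEPTION_WINDOW_S,
        "humanness": tuple(config.humanness_window_s),
        **TIMECOURSE_WINDOWS,
    }
    tab_p = spectral.erd(percep, roi, config.bands, windows)
    tab_r = spectral.erd(prod, roi, config.bands, {"analysis": PRODUCTION_WINDOW_S})
    tab_p["phase"] = "perception"
    tab_r["phase"] = "production"
    emg = {
        "perception": float(np.mean(spectral.emg_band_power(percep))),
        "production": float(np.mean(spectral.emg_band_power(prod))),
    }
    counts = {
        "perception_kept": int(percep.kept.sum()),
        "perception_total": int(percep.n_trials),
        "production_kept": int(prod.kept.sum()),
        "production_total": int(prod.n_trials),
    }
    per_trial = None
    if config.feature_regression:
        # per-trial fronto-central band power (vocal trials feed the
        # stimulus-feature regression)
        tt = spectral.trial_band_powers(
            percep, list(FRONTOCENTRAL_6), config.bands,
            {"stim": tuple(config.humanness_window_s)},
        )
        per_trial = (
            tt.groupby(["trial_index", "condition", "band"], as_index=False)
            .power.mean()
        )
    return pd.concat([tab_p, tab_r], ignore_index=True), emg, counts, per_trial


def _score_participant(profile, melodies, conditions, seed, nonvocal_ratio=60.0 / 52.0):
    """Sung-response scores per condition for one participant."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(len(melodies))
    devs = {"vocal": [], "nonvocal": []}
    n_excluded = 0
    for mel, cond, s in zip(melodies, conditions, seeds):
        inacc = profile.vocal_inaccuracy_cents * (1.0 if cond == "vocal" else nonvocal_ratio)
        track = cohort.simulate_sung_response(
            profile, mel, rng_seed=np.random.default_rng(s), inaccuracy_cents=inacc
        )
        score = acoustics.score_accuracy(track, mel)
        if score.excluded:
            n_excluded += 1
        else:
            devs[cond].extend(score.deviations)
    return (
        {c: float(np.mean(v)) if v else np.nan for c, v in devs.items()},
        {c: len(v) for c, v in devs.items()},
        n_excluded,
    )


def _first_sig_window(tc: pd.DataFrame, persist: int = 2) -> float:
    """Estimated ERD onset from the 1-s time-course windows.

    The detection statistic for window w >= 2 is each participant's band
    power in w minus their power in the first window (which precedes every
    configured onset): a paired drop that cancels both the baseline level
    and its sampling noise — the noisy 0.5 s baseline estimate is shared
    by all windows of a trial, so ERD-vs-baseline tests are correlated
    across windows and false-fire together at small n.  The onset is the
    first window whose group-mean drop is below -2 SE (SE across
    participants) for ``persist`` consecutive windows (a run may end at
    the last window).  Returns inf when no onset is detected; an onset
    inside the first window is not resolvable by construction.
    """
    tc = tc.copy()
    tc["power"] = tc.erd_uv2hz + tc.baseline_uv2hz
    per = tc.pivot_table(index="participant", columns="window", values="power")
    order = sorted(per.columns)
    ref = per[order[0]]
    sig = [False]
    for w in order[1:]:
        d = per[w] - ref
        se = d.std(ddof=1) / np.sqrt(len(d))
        sig.append(se > 0 and d.mean() < -2 * se)
    for i, w in enumerate(order):
        run = sig[i:i + persist]
        if len(run) == persist and all(run):
            return float(w[1:]) if isinstance(w, str) else float(w)
    return np.inf


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Run the full synthetic study and return the report bundle.

    The bundle holds the regional ERD table, the fronto-central
    time-course table, per-participant accuracy scores, the group
    statistics, and a ground-truth-vs-estimate recovery summary.  With
    ``out_dir`` set, tables are written as CSV and the report as JSON,
    each embedding the config hash and seed.
    """
    t_start = time.time()
    if config.n_participants < 6:
        warnings.warn(
            f"n={config.n_participants} gives very low statistical power; "
            "group tests are reported but unreliable"
        )
    ss = np.random.SeedSequence(config.seed)
    s_cohort, s_sched, s_mel, s_eeg, s_score = ss.spawn(5)
    erd_gt = ErdGroundTruth(params=dict(config.erd_overrides))
    profiles = cohort.make_cohort(
        config.n_participants,
        rng_seed=np.random.default_rng(s_cohort),
        coupling_rho=config.coupling_rho,
        erd=erd_gt,
    )
    melodies = melody.generate_melody_set(
        config.n_trials, rng_seed=int(s_mel.generate_state(1)[0] % 2**31)
    )

    eeg_seeds = s_eeg.spawn(len(profiles))
    sched_seeds = s_sched.spawn(len(profiles))
    score_seeds = s_score.spawn(len(profiles))
    erd_rows, acc_rows, emg_rows, trial_rows = [], [], [], []
    counts_log = []
    for i, prof in enumerate(profiles):
        schedule = cohort.make_schedule(
            config.n_trials, rng_seed=np.random.default_rng(sched_seeds[i])
        )
        t0 = time.time()
        tab, emg, counts, per_trial = _participant_erd(
            prof, schedule, erd_gt, config, np.random.default_rng(eeg_seeds[i])
        )
        if per_trial is not None:
            per_trial["participant"] = prof.id
            trial_rows.append(per_trial)
        tab["participant"] = prof.id
        erd_rows.append(tab)
        emg_rows.append({"participant": prof.id, **emg})
        counts_log.append({"participant": prof.id, **counts})
        scores, n_int, n_excl = _score_participant(
            prof,
            melodies[: config.n_melodies_scored],
            schedule.conditions[: config.n_melodies_scored],
            score_seeds[i],
        )
        acc_rows.append(
            {
                "participant": prof.id,
                "vocal_cents": scores["vocal"],
                "nonvocal_cents": scores["nonvocal"],
                "n_intervals_vocal": n_int["vocal"],
                "n_intervals_nonvocal": n_int["nonvocal"],
                "n_excluded_melodies": n_excl,
                "true_inaccuracy_cents": prof.vocal_inaccuracy_cents,
                "true_beta_effect": prof.beta_humanness_effect,
            }
        )
        log.info("participant %s done in %.1fs (kept %d/%d perception epochs)",
                 prof.id, time.time() - t0,
                 counts["perception_kept"], counts["perception_total"])

    erd_table = pd.concat(erd_rows, ignore_index=True)
    accuracy = pd.DataFrame(acc_rows)
    emg_table = pd.DataFrame(emg_rows)

    report = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "counts": counts_log,
        "stats": {},
        "recovery": {},
    }

    # --- group statistics ----------------------------------------------
    an = erd_table[(erd_table.window == "analysis")].copy()
    an["condition_pp"] = np.where(an.phase == "production", "production", "perception")
    stats_out = report["stats"]

    # production vs perception ANOVA per band
    for band in config.bands:
        sub = an[an.band == band].groupby(
            ["participant", "condition_pp", "hemisphere", "region_class"],
            as_index=False,
        ).erd_uv2hz.mean()
        try:
            res = stats.rm_anova(
                sub, "erd_uv2hz", "participant",
                ["condition_pp", "hemisphere", "region_class"],
            )
            stats_out[f"prod_vs_percep_{band}"] = _anova_json(res)
        except ValueError as e:
            stats_out[f"prod_vs_percep_{band}"] = {"error": str(e)}

    # humanness ANOVA per band (perception only)
    humanness_tables = {}
    for band in config.bands:
        sub = an[(an.band == band) & (an.phase == "perception")].groupby(
            ["participant", "condition", "hemisphere", "region_class"],
            as_index=False,
        ).erd_uv2hz.mean()
        humanness_tables[band] = sub
        try:
            res = stats.rm_anova(
                sub, "erd_uv2hz", "participant",
                ["condition", "hemisphere", "region_class"],
            )
            out = _anova_json(res)
            ph = stats.posthoc(res, "condition*region_class", "tukey_hsd")
            out["posthoc_condition_x_region"] = ph.to_dict("records")
            stats_out[f"humanness_{band}"] = out
        except ValueError as e:
            stats_out[f"humanness_{band}"] = {"error": str(e)}

    # fronto-central time course: Humanness x Time, Fisher LSD post-hoc
    tc_all = erd_table[
        erd_table.window.str.match("w[1-5]") & (erd_table.region_class == "fc")
    ]
    for band in config.bands:
        sub = tc_all[tc_all.band == band].groupby(
            ["participant", "condition", "window"], as_index=False
        ).erd_uv2hz.mean()
        try:
            res = stats.rm_anova(sub, "erd_uv2hz", "participant", ["condition", "window"])
            out = _anova_json(res)
            out["posthoc_lsd"] = stats.posthoc(
                res, "condition*window", "fisher_lsd"
            ).to_dict("records")
            stats_out[f"timecourse_{band}"] = out
        except ValueError as e:
            stats_out[f"timecourse_{band}"] = {"error": str(e)}

    # EMG: production vs perception paired t-test
    from scipy import stats as sps
    t_emg = sps.ttest_rel(emg_table.production, emg_table.perception)
    stats_out["emg_prod_vs_percep"] = {
        "t": float(t_emg.statistic), "p": float(t_emg.pvalue),
        "df": len(emg_table) - 1,
    }

    # accuracy: Wilcoxon vocal vs nonvocal; Spearman with humanness effect
    ok = accuracy.dropna(subset=["vocal_cents", "nonvocal_cents"])
    try:
        W, pW = stats.wilcoxon_paired(ok.vocal_cents, ok.nonvocal_cents)
        stats_out["accuracy_wilcoxon"] = {
            "W": W, "p": pW,
            "median_vocal": float(ok.vocal_cents.median()),
            "median_nonvocal": float(ok.nonvocal_cents.median()),
        }
    except ValueError as e:
        stats_out["accuracy_wilcoxon"] = {"error": str(e)}

    hum = erd_table[
        (erd_table.window == "humanness") & (erd_table.region_class == "fc")
        & (erd_table.band == "beta") & (erd_table.phase == "perception")
    ].pivot_table(index="participant", columns="condition", values="erd_uv2hz")
    hum["effect"] = hum["nonvocal"] - hum["vocal"]
    merged = accuracy.set_index("participant").join(hum)
    try:
        corr = stats.spearman(
            merged.vocal_cents, merged.effect,
            rng_seed=int(ss.generate_state(1)[0] % 2**31),
        )
        stats_out["accuracy_vs_humanness"] = {
            "rho": corr.rho, "n": corr.n, "p": corr.p,
        }
    except ValueError as e:
        stats_out["accuracy_vs_humanness"] = {"error": str(e)}

    # stimulus-feature regression: per-stimulus acoustic descriptors of
    # the vocal-like renditions vs mean fronto-central band power across
    # participants for the trials where that stimulus was heard as vocal
    if config.feature_regression and trial_rows:
        trial_tbl = pd.concat(trial_rows, ignore_index=True)
        vocal_tbl = trial_tbl[trial_tbl.condition == "vocal"]
        desc_rows = []
        for i, mel in enumerate(melodies):
            clip = synth.synth_vocal_like(
                mel, rng_seed=int(s_mel.generate_state(1)[0] % 2**31) + i
            )
            j, s_, f0sd, dur = acoustics.jitter_shimmer(clip)
            desc_rows.append((i, j, s_, f0sd, dur))
        desc = pd.DataFrame(
            desc_rows,
            columns=["trial_index", "jitter", "shimmer", "f0_variation",
                     "median_duration"],
        ).set_index("trial_index")
        for band in config.bands:
            resp = (
                vocal_tbl[vocal_tbl.band == band]
                .groupby("trial_index").power.mean()
            )
            common = desc.index.intersection(resp.index)
            try:
                stats_out[f"feature_regression_{band}"] = stats.feature_regression(
                    desc.loc[common],
                    resp.loc[common],
                    ["jitter", "shimmer", "f0_variation", "median_duration"],
                )
            except ValueError as e:
                stats_out[f"feature_regression_{band}"] = {"error": str(e)}

    # --- recovery summary ----------------------------------------------
    rec = report["recovery"]
    for band in config.bands:
        for cond in ("vocal", "nonvocal"):
            tc = tc_all[(tc_all.band == band) & (tc_all.condition == cond)]
            tc = tc.groupby(["participant", "window"], as_index=False)[
                ["erd_uv2hz", "baseline_uv2hz"]
            ].mean()
            rec[f"onset_window_{band}_{cond}"] = _first_sig_window(tc)
        rec[f"onset_vocal_earlier_{band}"] = bool(
            rec[f"onset_window_{band}_vocal"] < rec[f"onset_window_{band}_nonvocal"]
        )
    rec.update(_depth_recovery(erd_table, erd_gt, config))
    report["accuracy_table"] = accuracy.to_dict("records")
    report["duration_s"] = time.time() - t_start

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {"config_hash": config.hash(), "seed": config.seed}
        for name, frame in (
            ("erd_table", erd_table), ("accuracy", accuracy), ("emg", emg_table),
        ):
            frame = frame.copy()
            for k, v in meta.items():
                frame[k] = v
            frame.to_csv(out_dir / f"{name}.csv", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default)
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
    report["erd_table"] = erd_table
    report["emg_table"] = emg_table
    report["accuracy"] = accuracy
    return report


def listening_recovery(
    n_cohorts: int = 50,
    n_participants: int = 6,
    n_trials: int = 30,
    seed: int = 0,
    band: str = "mu",
) -> pd.DataFrame:
    """Listening-phase parameter recovery over many small cohorts.

    For each simulated cohort, runs the perception branch of the pipeline
    (highpass, re-reference, blink regression, stimulus-locked epoching,
    rejection, fronto-central time-course ERD) and estimates, per
    condition, the ERD onset window (first 1-s window with group-mean ERD
    below -2 SE) and the fractional band-power drop 1 - P_w5 / P_w1.

    Returns one row per cohort with columns ``onset_vocal, onset_nonvocal,
    drop_vocal, drop_nonvocal``.
    """
    erd_gt = ErdGroundTruth()
    roi = RoiSpec(regions={
        "fc_l": RoiSpec().regions["fc_l"], "fc_r": RoiSpec().regions["fc_r"],
    })
    ss = np.random.SeedSequence(seed)
    rows = []
    for cs in ss.spawn(n_cohorts):
        s_coh, s_sch, s_eeg = cs.spawn(3)
        profiles = cohort.make_cohort(
            n_participants, rng_seed=np.random.default_rng(s_coh), erd=erd_gt
        )
        eeg_seeds = s_eeg.spawn(n_participants)
        tabs = []
        for i, prof in enumerate(profiles):
            schedule = cohort.make_schedule(
                n_trials, rng_seed=np.random.default_rng(s_sch.spawn(1)[0])
            )
            raw = cohort.simulate_eeg(
                prof, schedule, erd=erd_gt,
                rng_seed=np.random.default_rng(eeg_seeds[i]),
            )
            raw = preprocess.highpass(raw)
            raw = preprocess.reref_mastoids(raw)
            raw = preprocess.remove_blinks(raw, "Fpz")
            ep = preprocess.epoch(raw, "stim", (1.0, 5.0))
            scalp = [c for c in raw.ch_names if c != "EMG"]
            ep = preprocess.reject_epochs(ep, channels=scalp)
            tab = spectral.erd(ep, roi, {band: DEFAULT_BANDS[band]},
                               TIMECOURSE_WINDOWS)
            tab["participant"] = prof.id
            tabs.append(tab)
        tc = pd.concat(tabs, ignore_index=True)
        tc = tc.groupby(["participant", "condition", "window"], as_index=False)[
            ["erd_uv2hz", "baseline_uv2hz"]
        ].mean()
        tc["power"] = tc.erd_uv2hz + tc.baseline_uv2hz
        row = {}
        for cond in ("vocal", "nonvocal"):
            sub = tc[tc.condition == cond]
            row[f"onset_{cond}"] = _first_sig_window(sub)
            per = sub.pivot_table(index="participant", columns="window", values="power")
            row[f"drop_{cond}"] = float((1.0 - per.w5 / per.w1).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def _depth_recovery(erd_table, erd_gt, config):
    """Estimate listening ERD depth from the fronto-central time course.

    The fractional band-power drop is measured as 1 - P_w5 / P_w1 (last vs
    first 1-s window, same spectral resolution, per participant then
    averaged) and compared with the configured 1 - (1 - depth)^2.  The mu
    band is used for the vocal/nonvocal contrast because its depth carries
    no per-participant effect.
    """
    out = {}
    tc = erd_table[
        erd_table.window.isin(["w1", "w5"]) & (erd_table.region_class == "fc")
        & (erd_table.phase == "perception")
    ].copy()
    tc["power"] = tc.erd_uv2hz + tc.baseline_uv2hz
    for band in config.bands:
        for cond in ("vocal", "nonvocal"):
            sub = tc[(tc.band == band) & (tc.condition == cond)]
            per = sub.pivot_table(index="participant", columns="window", values="power")
            if not {"w1", "w5"} <= set(per.columns):
                continue
            drop = float((1.0 - per.w5 / per.w1).mean())
            p = erd_gt.get(band, "fc", cond)
            expected = 1.0 - (1.0 - p.depth) ** 2
            out[f"depth_drop_{band}_{cond}"] = {
                "measured": drop, "expected_no_participant_effect": expected,
            }
    return out


def _anova_json(res) -> dict:
    return {
        e.name: {
            "F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p,
            "gg_epsilon": e.gg_epsilon, "p_gg": e.p_gg,
        }
        for e in res.effects.values()
    }


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))
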