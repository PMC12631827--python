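"""End-to-end demo pipeline: simulate -> analyze -> report.

Runs the full analysis chain on synthetic data with planted,
deactivation-like structure, in the order the analyses build on each other:
traveling waves, changepoint localization of the temporal boundary,
decoding (within-modality, cross-modal, feature-level), representational
similarity with decoupling, and the deactivation index with its behavioral
correlates and the mediation model.

Every stage draws from its own named substream of the root seed, writes its
outputs as JSON/CSV into the report directory, and contributes to a
manifest of content hashes — rerunning with the same config is
byte-identical, and toggling one stage off leaves the other stages' outputs
untouched.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import substream
from .changepoint import locate_boundary
from .config import RunConfig
from .containers import MIDLINE_AXIS
from .decoding import cross_modal_decode, cv_decode, feature_decode_4class
from .inferstats import (
    BehaviorDeltas,
    PhaseBetas,
    brain_behavior_correlation,
    deactivation_index,
    mediation_bootstrap,
)
from .io import write_json
from .rsa import (
    RDM,
    model_comparison,
    neural_rdm,
    rdm_to_rsm,
    feature_rdm,
    steiger_decoupling,
)
from .synthgen import (
    MediationSpec,
    PatternSpec,
    WaveSpec,
    gen_auc_curve,
    gen_beta_patterns,
    gen_behavior,
    gen_mediation_data,
    gen_phase_betas,
    gen_wave_eeg,
)
from .travelwave import band_power, build_axis_map, condition_contrast, wave_spectrum

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def _stage_waves(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.waves
    rng = substream(cfg.seed, "waves")
    per_trial_rows = []
    bands_by_cond = {}
    for cond, amp in (("IH", c.amplitude_ih), ("NP", c.amplitude_np)):
        spec = WaveSpec(
            frequency_hz=c.frequency_hz,
            direction="forward",
            amplitude=amp,
            phase_step_rad_per_channel=c.phase_step_rad_per_channel,
            noise_sd=c.noise_sd,
            seed=_seed(rng),
        )
        epochs = gen_wave_eeg(
            spec, n_channels=c.n_channels, duration_s=c.duration_s, fs_hz=c.fs_hz,
            n_trials=c.n_trials,
        )
        axis = MIDLINE_AXIS if c.n_channels == 7 else epochs.channel_names
        bands_by_cond[cond] = {b: [] for b in c.bands}
        for t in range(epochs.n_trials):
            ws = wave_spectrum(build_axis_map(epochs, axis, t))
            for b in c.bands:
                bp = band_power(ws, b)
                bands_by_cond[cond][b].append(bp)
                per_trial_rows.append((cond, t, b, bp.fw_db, bp.bw_db))

    pd.DataFrame(
        per_trial_rows, columns=["condition", "trial", "band", "fw_db", "bw_db"]
    ).to_csv(outdir / "waves_per_trial.csv", index=False)

    contrasts = {}
    for b in c.bands:
        res = condition_contrast(bands_by_cond["IH"][b], bands_by_cond["NP"][b])
        contrasts[b] = {
            "mean_delta_fw_db": res.mean_delta_fw,
            "t_fw": res.t_fw,
            "p_fw": res.p_fw,
            "mean_delta_bw_db": res.mean_delta_bw,
            "t_bw": res.t_bw,
            "p_bw": res.p_bw,
            "n_pairs": res.n_pairs,
        }
    alpha_ih = bands_by_cond["IH"]["alpha"] if "alpha" in c.bands else []
    summary = {
        "planted_frequency_hz": c.frequency_hz,
        "contrasts_ih_minus_np": contrasts,
        "mean_fw_minus_bw_db_alpha_ih": (
            float(np.mean([bp.fw_db - bp.bw_db for bp in alpha_ih])) if alpha_ih else None
        ),
    }
    write_json(summary, outdir / "waves.json")
    return summary


def _stage_changepoint(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.changepoint
    rng = substream(cfg.seed, "changepoint")
    change_index = int(round(c.change_time_s * c.fs_hz))
    curve = gen_auc_curve(
        c.n_samples, change_index, c.level_pre, c.level_post, c.noise_sd, seed=_seed(rng)
    )
    pd.DataFrame({"auc": curve}).to_csv(outdir / "changepoint_curve.csv", index=False)
    res = locate_boundary(curve, fs=c.fs_hz, window=c.window, min_size=c.min_size)
    out = {
        "planted_change_time_s": c.change_time_s,
        "boundary_time_s": res.time_s,
        "boundary_index": res.index,
        "reliable": res.reliable,
        "total_cost": res.segmentation.total_cost,
    }
    write_json(out, outdir / "changepoint.json")
    return out


def _stage_decoding(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.decoding
    rng = substream(cfg.seed, "decoding")
    structure_seed = _seed(rng)
    base = dict(
        n_trials_per_condition=c.n_trials_per_condition,
        n_runs=c.n_runs,
        n_features=c.n_features,
        condition_separation=c.condition_separation,
        feature_coupling=c.feature_coupling,
        noise_sd=c.noise_sd,
    )
    auditory = gen_beta_patterns(
        PatternSpec(**base, seed=_seed(rng)), structure_seed=structure_seed
    )
    visual = gen_beta_patterns(
        PatternSpec(**base, seed=_seed(rng)), structure_seed=structure_seed
    )

    loro = cv_decode(
        auditory, scheme="leave_one_run_out", n_boot=c.n_boot,
        n_components=c.n_components, seed=_seed(rng), metric="auc",
    )
    xmod = cross_modal_decode(
        auditory, visual, n_components=c.n_components, n_boot=c.n_boot,
        seed=_seed(rng), metric="auc",
    )
    feature_trials = gen_beta_patterns(
        PatternSpec(
            **{**base, "n_trials_per_condition": c.feature_trials_per_condition,
               "feature_coupling": max(c.feature_coupling, 0.5)},
            seed=_seed(rng),
        )
    )
    feat = feature_decode_4class(
        feature_trials, "rating", n_components=c.n_components, n_boot=c.n_boot,
        seed=_seed(rng),
    )
    out = {
        "loro_auc": loro.mean,
        "crossmodal_auc": xmod.mean,
        "feature4_accuracy": feat.mean,
        "chance_binary": loro.chance,
        "chance_feature4": feat.chance,
        "n_boot": c.n_boot,
    }
    write_json(out, outdir / "decoding.json")
    return out


def _stage_rsa(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.rsa
    rng = substream(cfg.seed, "rsa")
    n_items = c.n_trials_per_condition
    ratings = rng.uniform(1.0, 9.0, n_items)

    per_condition = {}
    for cond, coupling in (("NP", c.coupling_np), ("IH", c.coupling_ih)):
        tbm = gen_beta_patterns(
            PatternSpec(
                n_trials_per_condition=n_items,
                n_runs=1,
                n_features=c.n_features,
                condition_separation=0.0,
                feature_coupling=coupling,
                noise_sd=1.0,
                seed=_seed(rng),
            ),
            feature_ratings=np.concatenate([ratings, ratings]),
        )
        per_condition[cond] = tbm.patterns[: n_items]

    f_rsm = rdm_to_rsm(feature_rdm(ratings))
    rsm_np = rdm_to_rsm(neural_rdm(per_condition["NP"]))
    rsm_ih = rdm_to_rsm(neural_rdm(per_condition["IH"]))
    dec = steiger_decoupling(f_rsm, rsm_np, rsm_ih)

    # Condition-structured dataset for the conceptual-model comparison.
    combined = gen_beta_patterns(
        PatternSpec(
            n_trials_per_condition=n_items,
            n_runs=1,
            n_features=c.n_features,
            condition_separation=2.0,
            feature_coupling=0.0,
            noise_sd=1.0,
            seed=_seed(rng),
        )
    )
    nr = neural_rdm(combined.patterns)
    same = combined.condition[:, None] == combined.condition[None, :]
    model = RDM(matrix=np.where(same, 0.0, 1.0))
    rho, p = model_comparison(nr, model, n_perm=c.n_perm, seed=_seed(rng))

    out = {
        "decoupling": {
            "r_np": dec.r_condition_a,
            "r_ih": dec.r_condition_b,
            "r_between": dec.r_ab,
            "delta_r": dec.delta_r,
            "z": dec.z,
            "p": dec.p,
            "n_pairs": dec.n_pairs,
        },
        "model_comparison": {"spearman_rho": rho, "p_perm": p, "n_perm": c.n_perm},
    }
    write_json(out, outdir / "rsa.json")
    return out


def _stage_inference(cfg: RunConfig, outdir: Path) -> dict:
    c = cfg.inference
    rng = substream(cfg.seed, "inference")
    betas = gen_phase_betas(
        c.n_subjects, c.pre_contrast, c.post_contrast, c.beta_noise_sd, seed=_seed(rng)
    )
    pb = PhaseBetas(**betas, region="sensory", boundary_s=c.boundary_s)
    idx = deactivation_index(pb)

    z_idx = (idx - idx.mean()) / idx.std()
    behavior = gen_behavior(
        c.n_subjects, c.p_np, c.p_ih, n_trials=c.n_behavior_trials,
        subject_sd=c.subject_sd, seed=_seed(rng),
        ih_logit_shift=c.behavior_neural_slope * z_idx,
    )
    rates = (
        behavior.groupby(["subject", "condition"])["response"].mean().unstack("condition")
    )
    delta = (rates["IH"] - rates["NP"]).to_numpy()
    deltas = BehaviorDeltas(dp_sensed=delta, dp_understood=delta, dacc_objective=delta)
    table = brain_behavior_correlation(idx, deltas, windows=None)
    table.to_csv(outdir / "brain_behavior.csv", index=False)

    med = gen_mediation_data(
        MediationSpec(
            n=c.mediation_n, path_a=c.mediation_a, path_b=c.mediation_b,
            path_c_prime=c.mediation_c_prime, seed=_seed(rng),
        )
    )
    pd.DataFrame({"X": med[0], "M": med[1], "Y": med[2]}).to_csv(
        outdir / "mediation_data.csv", index=False
    )
    mres = mediation_bootstrap(*med, n_boot=c.n_boot, seed=_seed(rng))

    r_main = float(table["r"].iloc[0])
    out = {
        "boundary_s": c.boundary_s,
        "deactivation_index_mean": float(idx.mean()),
        "deactivation_index_sd": float(idx.std(ddof=1)),
        "planted_index": c.post_contrast - c.pre_contrast,
        "brain_behavior_r": r_main,
        "brain_behavior_p_fdr": float(table["p_fdr"].iloc[0]),
        "mediation": {
            "a": mres.a,
            "b": mres.b,
            "c_prime": mres.c_prime,
            "c": mres.c,
            "indirect": mres.indirect,
            "ci_low": mres.ci_low,
            "ci_high": mres.ci_high,
            "n_boot": mres.n_boot,
            "significant": mres.significant,
        },
        "n_subjects": c.n_subjects,
    }
    write_json(out, outdir / "inference.json")
    return out


_STAGES = [
    ("waves", _stage_waves),
    ("changepoint", _stage_changepoint),
    ("decoding", _stage_decoding),
    ("rsa", _stage_rsa),
    ("inference", _stage_inference),
]


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all enabled stages; write per-stage outputs plus a manifest.

    Returns the in-memory report (one entry per stage).  Any stage failure
    halts the run with the stage named; outputs of earlier stages are left
    in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    for name, fn in _STAGES:
        if not getattr(config, name).enabled:
            logger.info("stage %s disabled; skipping", name)
            continue
        logger.info("running stage %s", name)
        try:
            report[name] = fn(config, outdir)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    write_json(manifest, outdir / "manifest.json")
    report["manifest"] = manifest
    return report
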