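"""End-to-end orchestration: simulate/load -> metrics -> PCA -> decoding.

A single configured run produces every stage artifact plus a
machine-readable ``report.json`` aggregating the headline numbers
(drift summary, regressions, PCA variance fractions, mean d' for all
versus reliable units, behavioural-decoding correlations, sensory-bias
mean).  All randomness derives from one master seed through named
streams, and report numbers are serialized at 12 significant digits so
determinism is byte-testable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, metrics, models, statespace, theory
from .session import Session, load_session, save_session, slice_repeats
from .synth import SynthConfig, simulate_session

__all__ = [
    "RunConfig",
    "run_pipeline",
    "run_model_suite",
    "derive_seed",
    "round_sig",
]

logger = logging.getLogger(__name__)

UNIFORM_SD = np.sqrt(1.0 / 12.0)  # SD of a uniform [0, 1] draw


def derive_seed(master_seed: int, key: str) -> int:
    """Stable per-purpose seed derived from the master seed.

    Streams are keyed by name so adding a stage never perturbs the
    seeds of earlier ones.  Result is below 2**31.
    """
    h = zlib.crc32(key.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed), h])
    return int(ss.generate_state(1)[0] % (2**31))


def round_sig(value, digits: int = 12):
    """Round floats (recursively through dict/list) to significant digits."""
    if isinstance(value, dict):
        return {k: round_sig(v, digits) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [round_sig(v, digits) for v in value]
    if isinstance(value, (float, np.floating)):
        v = float(value)
        if not np.isfinite(v) or v == 0.0:
            return v
        return float(f"{v:.{digits}g}")
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, np.ndarray):
        return round_sig(value.tolist(), digits)
    return value


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input mode: ``synth_config`` (simulate) or
    ``session_path`` (load).
    """

    synth_config: SynthConfig | None = None
    session_path: str | None = None
    stimulus: str = "natural_movie_1"
    regions: str | None = None
    use_zscore: bool = False
    reliable_threshold: float = 0.5
    ridge: float = 1.0
    n_pcs: int = 10
    master_seed: int = 0
    n_shuffles: int = 100

    def __post_init__(self) -> None:
        if (self.synth_config is None) == (self.session_path is None):
            raise ValueError(
                "exactly one of synth_config and session_path required"
            )

    def config_hash(self) -> str:
        payload = {
            "synth": self.synth_config.to_dict() if self.synth_config else None,
            "session_path": self.session_path,
            "stimulus": self.stimulus,
            "regions": self.regions,
            "use_zscore": self.use_zscore,
            "reliable_threshold": self.reliable_threshold,
            "ridge": self.ridge,
            "n_pcs": self.n_pcs,
            "master_seed": self.master_seed,
            "n_shuffles": self.n_shuffles,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_metrics(session: Session, config: RunConfig, out: Path) -> dict:
    tensor = slice_repeats(
        session, config.stimulus, regions=config.regions,
        use_zscore=config.use_zscore,
    )
    vectors = metrics.population_vectors(tensor)
    rs = metrics.rs_matrix(vectors, blocks=tensor.blocks)
    summary = metrics.drift_summary(rs)
    reliability = metrics.stimulus_reliability(tensor)
    pupil = metrics.repeat_behavior_means(session, tensor, "pupil_width")
    running = metrics.repeat_behavior_means(session, tensor, "running_speed")
    reg = metrics.rs_vs_pupil_regression(rs, pupil, running)
    reg_run = metrics.rs_vs_pupil_regression(
        rs, pupil, running, running_percentile=80.0
    )
    # behavioural tuning per unit across the whole session
    pupil_trace = session.behavior["pupil_width"].to_numpy(float)
    run_trace = session.behavior["running_speed"].to_numpy(float)
    tuning = pd.DataFrame(
        {
            "unit_id": session.units["unit_id"],
            "rho_pupil": [
                metrics.behavior_correlation(session.counts[i], pupil_trace)
                for i in range(session.n_units)
            ],
            "rho_running": [
                metrics.behavior_correlation(session.counts[i], run_trace)
                for i in range(session.n_units)
            ],
        }
    )
    pd.DataFrame(rs.rho).to_csv(out / "rs_matrix.csv", index=False,
                                header=False)
    reliability.to_csv(out / "reliability.csv", index=False)
    tuning.to_csv(out / "behavior_tuning.csv", index=False)
    (out / "drift_summary.json").write_text(
        json.dumps(round_sig(vars(summary)), sort_keys=True)
    )
    return {
        "tensor": tensor,
        "rs": rs,
        "summary": summary,
        "reliability": reliability,
        "tuning": tuning,
        "pupil_means": pupil,
        "report": {
            "cc_within": summary.cc_within,
            "cc_between": summary.cc_between,
            "rdi": summary.rdi,
            "rs_vs_pupil_slope": reg["slope"],
            "rs_vs_pupil_r2": reg["r2"],
            "rs_vs_pupil_slope_run80": reg_run["slope"],
        },
    }


def _stage_pca(session: Session, config: RunConfig, tensor, reliability,
               out: Path) -> dict:
    bins = np.sort(tensor.bins.ravel())
    activity = session.counts[:, bins]
    pca = statespace.pca_population(activity, n_pcs=config.n_pcs)
    pupil = session.behavior["pupil_width"].to_numpy(float)[bins]
    pc1 = pca.scores[0]
    corr = metrics.behavior_correlation(pc1, pupil)
    rel = reliability["reliability"].to_numpy(float)
    mean_act = reliability["setpoint"].to_numpy(float)
    fit_rel = statespace.loading_vs_unit_property(pca.loadings[0], rel)
    fit_mean = statespace.loading_vs_unit_property(pca.loadings[0], mean_act)
    pd.DataFrame(
        {
            "pc": np.arange(1, pca.n_components + 1),
            "explained_variance_ratio": pca.explained_variance_ratio,
        }
    ).to_csv(out / "pca_variance.csv", index=False)
    pd.DataFrame(pca.loadings.T, columns=[
        f"pc{i+1}" for i in range(pca.n_components)
    ]).to_csv(out / "pca_loadings.csv", index=False)
    return {
        "pca": pca,
        "report": {
            "pc1_variance_fraction": float(pca.explained_variance_ratio[0]),
            "pc1_pupil_correlation": corr,
            "loading_vs_reliability_r2": fit_rel["r2"],
            "loading_vs_mean_activity_r2": fit_mean["r2"],
        },
    }


def _stage_decoding(session: Session, config: RunConfig, tensor, reliability,
                    tuning, out: Path) -> dict:
    blocks = np.unique(tensor.blocks)
    if len(blocks) != 2:
        raise ValueError("decoding stage expects two blocks")
    train_mask = tensor.blocks == blocks[0]
    test_mask = tensor.blocks == blocks[1]
    train = _subset_repeats(tensor, train_mask)
    test = _subset_repeats(tensor, test_mask)

    def mean_dprime(unit_mask: np.ndarray | None) -> float:
        tr = train if unit_mask is None else decoding.subset_tensor(
            train, unit_mask)
        te = test if unit_mask is None else decoding.subset_tensor(
            test, unit_mask)
        model = decoding.train_frame_decoder(tr, ridge=config.ridge)
        return decoding.dprime_matrix(model, te).mean_off_diagonal()

    sel = decoding.select_reliable_units(
        reliability, threshold=config.reliable_threshold
    )
    rel_table = reliability.copy()
    rel_table["abs_rho_pupil"] = tuning["rho_pupil"].abs().to_numpy()
    n_rel = sel["n_selected"]
    if n_rel:
        beh_thresh = float(
            np.sort(rel_table["abs_rho_pupil"].to_numpy())[-n_rel]
        )
        sel_beh = decoding.select_reliable_units(
            rel_table, threshold=beh_thresh - 1e-12, by="abs_rho_pupil"
        )
    else:
        sel_beh = {"mask": np.zeros(session.n_units, bool), "n_selected": 0,
                   "session_included": False}
    d_all = mean_dprime(None)
    d_rel = mean_dprime(sel["mask"]) if sel["n_selected"] else np.nan
    d_beh = mean_dprime(sel_beh["mask"]) if sel_beh["n_selected"] else np.nan

    model_all = decoding.train_frame_decoder(train, ridge=config.ridge)
    dmat = decoding.dprime_matrix(model_all, test)
    pd.DataFrame(dmat.dprime).to_csv(out / "dprime_matrix.csv", index=False,
                                     header=False)

    beh = decoding.train_behavior_decoder(
        tensor,
        {
            "pupil_width": session.behavior["pupil_width"].to_numpy(float),
            "running_speed": session.behavior["running_speed"].to_numpy(float),
        },
        ridge=config.ridge,
        split_seed=derive_seed(config.master_seed, "behavior-decoder-split"),
    )
    bias = decoding.sensory_bias_check(
        beh["weights"][0], tensor, beh["input_mean"], beh["input_sd"]
    )
    report = {
        "mean_dprime_all_units": d_all,
        "mean_dprime_reliable_units": d_rel,
        "mean_dprime_behavior_selected": d_beh,
        "n_reliable_units": sel["n_selected"],
        "session_included": sel["session_included"],
        "behavior_decoding_correlations": beh["correlations"],
        "sensory_bias_mean_correlation": bias["mean_correlation"],
    }
    (out / "dprime_summary.json").write_text(
        json.dumps(round_sig({
            k: v for k, v in report.items()
            if k.startswith(("mean_dprime", "n_reliable", "session"))
        }), sort_keys=True)
    )
    (out / "behavior_decoding.json").write_text(
        json.dumps(round_sig({
            "correlations": beh["correlations"],
            "sensory_bias_mean_correlation": bias["mean_correlation"],
        }), sort_keys=True)
    )
    return {"report": report}


def _subset_repeats(tensor, mask):
    from .session import RepeatTensor

    return RepeatTensor(
        data=tensor.data[mask],
        blocks=tensor.blocks[mask],
        unit_ids=tensor.unit_ids,
        stimulus_name=tensor.stimulus_name,
        bins=None if tensor.bins is None else tensor.bins[mask],
    )


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis pipeline and write ``report.json``.

    Stages run in fixed order (input, metrics, PCA, decoding); a stage
    failure aborts the run with the failing stage named, retaining
    partial outputs under ``failed/``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("driftlab")
    root.addHandler(handler)
    stage = "input"
    try:
        if config.synth_config is not None:
            seed = derive_seed(config.master_seed, "simulate")
            session, truth = simulate_session(config.synth_config, seed)
            save_session(session, out / "session", overwrite=True)
        else:
            session = load_session(config.session_path)
            truth = None
        stage = "metrics"
        m = _stage_metrics(session, config, out)
        stage = "pca"
        p = _stage_pca(session, config, m["tensor"], m["reliability"], out)
        stage = "decoding"
        d = _stage_decoding(
            session, config, m["tensor"], m["reliability"], m["tuning"], out
        )
    except Exception:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "stage.txt").write_text(stage)
        logger.error("pipeline failed in stage %r", stage)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    report = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "stimulus": config.stimulus,
        "metrics": m["report"],
        "pca": p["report"],
        "decoding": d["report"],
    }
    report = round_sig(report, 12)
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1)
    )
    logger.info("pipeline complete: %s", out / "report.json")
    return report


# --- model comparison suite ---------------------------------------------


def _theory_mean(variant: str, behavior: np.ndarray,
                 refresh_tuning: bool = False) -> float:
    """Mean closed-form RS over all repeat pairs of a simulation."""
    s = n = t = UNIFORM_SD
    iu, ju = np.triu_indices(len(behavior), k=1)
    bi, bj = behavior[iu], behavior[ju]
    if variant == "both":
        vals = np.full(len(bi), theory.rs_both_scaled(s, n, 1.0, 1.0))
    elif variant == "signal":
        vals = np.array([
            theory.rs_signal_scaled(s, n, x, y) for x, y in zip(bi, bj)
        ])
    elif variant == "noise":
        vals = np.array([
            theory.rs_noise_scaled(s, n, x, y) for x, y in zip(bi, bj)
        ])
    elif variant == "independent":
        fn = (
            theory.rs_independent
            if refresh_tuning
            else theory.rs_independent_frozen_tuning
        )
        vals = np.array([fn(s, t, n, x, y) for x, y in zip(bi, bj)])
    else:
        raise ValueError(variant)
    return float(vals.mean())


def run_model_suite(seed: int, out_dir: str | Path | None = None,
                    n_sims: int = 3) -> dict:
    """Run all repeat-level models at reference parameters.

    Emits RS-versus-relative-behaviour curves, the reliability /
    behavioural-modulation regressions for the extended-gain and
    independent models, and a theory-versus-Monte-Carlo deviation
    table (averaged over ``n_sims`` independent simulations to beat
    down the frozen-draw sampling error).
    """
    rows = []
    curves = {}
    for variant in ("both", "signal", "noise"):
        devs = []
        for k in range(n_sims):
            params = models.GainModelParams(
                variant=variant, seed=derive_seed(seed, f"gain-{variant}-{k}")
            )
            resp = models.simulate_gain_model(params)
            rho = models.repeat_rs_matrix(resp)
            iu, ju = np.triu_indices(resp.n_repeats, k=1)
            mc = float(rho[iu, ju].mean())
            th = _theory_mean(variant, resp.behavior)
            devs.append(mc - th)
            if k == 0:
                curves[variant] = models.rs_vs_relative_behavior(resp)
        rows.append({"model": f"gain_{variant}",
                     "mc_minus_theory": float(np.mean(devs))})
    devs = []
    for k in range(n_sims):
        params = models.IndependentModelParams(
            seed=derive_seed(seed, f"independent-{k}")
        )
        resp = models.simulate_independent(params)
        rho = models.repeat_rs_matrix(resp)
        iu, ju = np.triu_indices(resp.n_repeats, k=1)
        mc = float(rho[iu, ju].mean())
        th = _theory_mean("independent", resp.behavior)
        devs.append(mc - th)
        if k == 0:
            curves["independent"] = models.rs_vs_relative_behavior(resp)
    rows.append({"model": "independent",
                 "mc_minus_theory": float(np.mean(devs))})

    ext = models.simulate_extended_gain(
        models.ExtendedGainParams(seed=derive_seed(seed, "extended"))
    )
    reg_ext = models.reliability_modulation_regression(ext)
    ind_ext = models.simulate_independent(
        models.IndependentModelParams(
            n_repeats=200, n_stimuli=10,
            seed=derive_seed(seed, "independent-extended"),
        )
    )
    reg_ind = models.reliability_modulation_regression(ind_ext)

    table = pd.DataFrame(rows)
    result = {
        "theory_deviation": table,
        "max_abs_deviation": float(table["mc_minus_theory"].abs().max()),
        "extended_gain_regression": reg_ext,
        "independent_regression": reg_ind,
        "r2_contrast": reg_ext["r2"] - reg_ind["r2"],
        "curves": curves,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "theory_deviation.csv", index=False)
        for name, curve in curves.items():
            pd.DataFrame(
                {
                    "bin_center": curve["bin_centers"],
                    "mean_rs": curve["bin_means"],
                }
            ).to_csv(out / f"rs_curve_{name}.csv", index=False)
        (out / "model_suite.json").write_text(
            json.dumps(
                round_sig(
                    {
                        "max_abs_deviation": result["max_abs_deviation"],
                        "extended_gain_r2": reg_ext["r2"],
                        "independent_r2": reg_ind["r2"],
                        "r2_contrast": result["r2_contrast"],
                    }
                ),
                sort_keys=True,
            )
        )
    return result
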