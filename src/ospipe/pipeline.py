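"""End-to-end orchestration: design -> simulate -> preprocess -> erp ->
decode -> stats, driven by a single YAML/JSON config and a master seed.

Every stage's randomness is derived from the master seed through fixed
spawn keys, so a run is reproducible from the config alone.  Each artifact
carries a provenance header (config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, decode, design, erp, preprocess, simulate, stats
from .io import write_csv_with_header


class PipelineConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_SECTIONS = ("design", "simulation", "preprocess", "erp", "decode", "stats")

# spawn keys for per-stage RNG streams
_SEED_KEYS = {"design": 0, "simulation": 1, "decode": 2, "cluster": 3}


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence((master, _SEED_KEYS[stage]))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def load_config(path: str | Path) -> dict:
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except Exception as exc:
        raise PipelineConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a mapping")
    return cfg


def load_preset(name: str) -> dict:
    with resources.files("ospipe.presets").joinpath(f"{name}.yaml").open() as fh:
        return yaml.safe_load(fh)


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(cfg: dict) -> "ResolvedConfig":
    """Build all module configs up front; raises PipelineConfigError."""
    unknown = set(cfg) - set(_SECTIONS) - {"seed", "output_dir", "save_epochs"}
    if unknown:
        raise PipelineConfigError(f"unknown config section(s): {sorted(unknown)}")
    try:
        seed = int(cfg.get("seed", 0))
        dsec = dict(cfg.get("design") or {})
        presentations = int(dsec.pop("presentations_per_melody", 20))
        omission_rate = float(dsec.pop("omission_rate", 0.5))
        if dsec:
            raise PipelineConfigError(f"unknown design key(s): {sorted(dsec)}")
        sim_kwargs = dict(cfg.get("simulation") or {})
        sim_kwargs.setdefault("seed", _stage_seed(seed, "simulation"))
        for key in ("epoch_span", "note_pattern_window_ms"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim = simulate.SimulationConfig(**sim_kwargs)
        pre_kwargs = dict(cfg.get("preprocess") or {})
        for key in ("band", "transition_bandwidth", "baseline_window",
                    "analysis_window"):
            if key in pre_kwargs and pre_kwargs[key] is not None:
                pre_kwargs[key] = tuple(pre_kwargs[key])
        if "roi" in pre_kwargs:
            pre_kwargs["roi"] = tuple(pre_kwargs["roi"])
        pre = preprocess.PreprocessConfig(**pre_kwargs)
        esec = dict(cfg.get("erp") or {})
        search = tuple(esec.pop("search", (50.0, 110.0)))
        half_width = float(esec.pop("half_width", 10.0))
        if esec:
            raise PipelineConfigError(f"unknown erp key(s): {sorted(esec)}")
        dec_kwargs = dict(cfg.get("decode") or {})
        dec_enabled = bool(dec_kwargs.pop("enabled", True))
        dec_kwargs.setdefault("seed", _stage_seed(seed, "decode"))
        if "decode_range" in dec_kwargs:
            dec_kwargs["decode_range"] = tuple(dec_kwargs["decode_range"])
        dec = decode.DecodeConfig(**dec_kwargs)
        ssec = dict(cfg.get("stats") or {})
        stat = StatsSection(
            n_permutations=int(ssec.pop("n_permutations", 10_000)),
            cluster_alpha=float(ssec.pop("cluster_alpha", 0.05)),
            tail=str(ssec.pop("tail", "two")),
            bf_prior_r=float(ssec.pop("bf_prior_r", 0.707)),
            chance=float(ssec.pop("chance", 0.25)),
            power=dict(ssec.pop("power", {"dz": 0.66, "alpha": 0.05,
                                          "power": 0.80})),
        )
        if ssec:
            raise PipelineConfigError(f"unknown stats key(s): {sorted(ssec)}")
    except PipelineConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise PipelineConfigError(str(exc)) from exc
    return ResolvedConfig(seed, presentations, omission_rate, sim, pre,
                          search, half_width, dec, dec_enabled, stat,
                          bool(cfg.get("save_epochs", False)),
                          config_hash(cfg))


@dataclass(frozen=True)
class StatsSection:
    n_permutations: int = 10_000
    cluster_alpha: float = 0.05
    tail: str = "two"
    bf_prior_r: float = 0.707
    chance: float = 0.25
    power: dict = field(default_factory=dict)


@dataclass
class ResolvedConfig:
    seed: int
    presentations_per_melody: int
    omission_rate: float
    simulation: simulate.SimulationConfig
    preprocess: preprocess.PreprocessConfig
    erp_search: tuple[float, float]
    erp_half_width: float
    decode: decode.DecodeConfig
    decode_enabled: bool
    stats: StatsSection
    save_epochs: bool
    cfg_hash: str

    def header(self) -> list[str]:
        return [f"ospipe {__version__}", f"config_hash {self.cfg_hash}",
                f"seed {self.seed}"]


@dataclass
class RunReport:
    output_dir: Path
    paths: dict[str, Path]
    window: erp.MeasurementWindow
    amplitude_table: pd.DataFrame
    accuracy_table: pd.DataFrame | None
    report: stats.StatReport
    included: dict[str, bool]


def run_pipeline(cfg: dict, output_dir: str | Path) -> RunReport:
    """Execute the full chain in memory, writing all tables and the report."""
    rc = validate_config(cfg)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = rc.header()
    paths: dict[str, Path] = {}

    # design ---------------------------------------------------------------
    try:
        schedule = design.build_schedule(
            design.default_specs_both_conditions(),
            rc.presentations_per_melody, rc.omission_rate,
            seed=_stage_seed(rc.seed, "design"))
        paths["schedule"] = out / "schedule.csv"
        write_csv_with_header(schedule.to_dataframe(), paths["schedule"],
                              header)
    except Exception as exc:
        raise StageError("design", exc) from exc

    # simulate -------------------------------------------------------------
    try:
        cohort, truth = simulate.simulate_cohort(rc.simulation, schedule)
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # preprocess -----------------------------------------------------------
    try:
        clean: list[dict[str, simulate.EpochSet]] = []
        logs = []
        included: dict[str, bool] = {}
        for epoch_sets in cohort:
            cleaned = {}
            ok = True
            for cond, eps in epoch_sets.items():
                ce, log = preprocess.preprocess_epochs(eps, rc.preprocess)
                cleaned[cond] = ce
                logs.append(log)
                decision = preprocess.check_inclusion(
                    ce.retained_counts(), schedule.scheduled_counts(cond),
                    rc.preprocess)
                ok = ok and decision.included
            pid = next(iter(epoch_sets.values())).participant_id
            included[pid] = ok
            clean.append(cleaned)
        rej = (pd.concat(logs, ignore_index=True) if logs else
               pd.DataFrame())
        paths["rejection_log"] = out / "rejection_log.csv"
        write_csv_with_header(rej, paths["rejection_log"], header)
        if rc.save_epochs:
            from .io import save_epochs
            epodir = out / "epochs"
            epodir.mkdir(exist_ok=True)
            for cleaned in clean:
                for cond, eps in cleaned.items():
                    save_epochs(eps,
                                epodir / f"{eps.participant_id}_{cond}.h5")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    # erp ------------------------------------------------------------------
    try:
        conditions = list(next(iter(clean)).keys())
        participant_waves = {c: [] for c in conditions}
        for cleaned in clean:
            for cond, eps in cleaned.items():
                participant_waves[cond].append(erp.average_epochs(eps))
        grand = {c: erp.grand_average(w) for c, w in participant_waves.items()}
        roi = rc.preprocess.roi
        window = erp.define_oN1_window(
            erp.roi_mean(grand["familiar"], roi),
            erp.roi_mean(grand["unfamiliar"], roi),
            grand["familiar"].time_axis, rc.erp_search, rc.erp_half_width)
        rows = []
        for cleaned in clean:
            for cond, eps in cleaned.items():
                wave = erp.average_epochs(eps)
                amp = erp.mean_amplitude(erp.roi_mean(wave, roi),
                                         wave.time_axis, window)
                rows.append((eps.participant_id, cond,
                             wave.n_epochs_averaged, amp))
        amp_table = erp.amplitude_table(rows)
        paths["amplitudes"] = out / "amplitudes.csv"
        write_csv_with_header(amp_table, paths["amplitudes"], header)
        for cond, g in grand.items():
            gdf = pd.DataFrame({"time_ms": g.time_axis,
                                "roi_uV": erp.roi_mean(g, roi)})
            p = out / f"grand_average_{cond}.csv"
            write_csv_with_header(gdf, p, header)
            paths[f"grand_average_{cond}"] = p
        (out / "window.json").write_text(json.dumps({
            "lo_ms": window.lo, "hi_ms": window.hi,
            "peak_latency_ms": window.peak_latency,
            "polarity": window.polarity,
            "at_search_edge": window.at_search_edge}, indent=2))
        paths["window"] = out / "window.json"
    except Exception as exc:
        raise StageError("erp", exc) from exc

    # decode ---------------------------------------------------------------
    acc_table = None
    series_by_cond: dict[str, list[decode.AccuracyTimeSeries]] = {}
    if rc.decode_enabled:
        try:
            all_series = []
            for cleaned in clean:
                pid = next(iter(cleaned.values())).participant_id
                if not included[pid]:
                    continue
                for cond, eps in cleaned.items():
                    s = decode.decode_timecourse(eps, rc.decode)
                    all_series.append(s)
                    series_by_cond.setdefault(cond, []).append(s)
            acc_table = decode.accuracy_long_table(all_series)
            paths["accuracy"] = out / "accuracy.csv"
            write_csv_with_header(acc_table, paths["accuracy"], header)
        except Exception as exc:
            raise StageError("decode", exc) from exc

    # stats ----------------------------------------------------------------
    try:
        report = stats.StatReport(seeds={"master": rc.seed})
        fam = amp_table.query("condition == 'familiar'").sort_values(
            "participant")["amplitude_uV"].to_numpy()
        unf = amp_table.query("condition == 'unfamiliar'").sort_values(
            "participant")["amplitude_uV"].to_numpy()
        t_amp = stats.paired_t_dz(fam, unf)
        report.add_ttest("oN1_familiar_vs_unfamiliar", t_amp,
                         stats.jzs_bf10(t_amp.t, t_amp.n, rc.stats.bf_prior_r))
        if series_by_cond:
            fam_s = series_by_cond["familiar"]
            unf_s = series_by_cond["unfamiliar"]
            a = np.stack([s.accuracy for s in fam_s])
            b = np.stack([s.accuracy for s in unf_s])
            cres = stats.cluster_permutation(
                a, b, fam_s[0].time_axis, rc.stats.n_permutations,
                rc.stats.cluster_alpha, rc.stats.tail,
                seed=_stage_seed(rc.seed, "cluster"))
            report.add_clusters(cres)
            sig = cres.significant()
            if sig:
                win = (sig[0].start_ms, sig[0].end_ms)
                for cond, slist in series_by_cond.items():
                    vals = np.array([decode.window_mean_accuracy(s, win)
                                     for s in slist])
                    t_acc = stats.one_sample_t_dz(vals, rc.stats.chance)
                    report.add_ttest(
                        f"decoding_{cond}_vs_chance_{win[0]:.0f}-{win[1]:.0f}ms",
                        t_acc, stats.jzs_bf10(t_acc.t, t_acc.n,
                                              rc.stats.bf_prior_r))
        if rc.stats.power:
            pres = stats.power_sample_size(**rc.stats.power)
            report.power = {"n_required": pres.n_required, "dz": pres.dz,
                            "alpha": pres.alpha, "power": pres.power,
                            "achieved_power": pres.achieved_power}
        paths["stat_report"] = out / "stat_report.json"
        report.to_json(paths["stat_report"])
        (out / "stat_report.txt").write_text(report.to_text() + "\n")
        paths["stat_report_txt"] = out / "stat_report.txt"
    except StageError:
        raise
    except Exception as exc:
        raise StageError("stats", exc) from exc

    return RunReport(out, paths, window, amp_table, acc_table, report,
                     included)
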