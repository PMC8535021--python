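"""End-to-end orchestration: simulate -> analyze -> pair -> stats -> report.

One call (or ``venticomp reproduce``) runs the whole synthetic study: 18
providers each perform a short (S1) and a long (S4) manikin scenario, a
duration-matched newborn episode is drawn for each, all waveforms go through
the breath-by-breath measurement pipeline, episodes are paired within ±15%
PPV duration and split into the MS/BS/ML/BL groups, and the statistical
layer produces median/IQR tables, panel random-effects comparisons with
Newey-West variance, LOESS trend curves, dynamical and Pearson correlations,
and the obstruction chi-square. Every numeric in the report is written to a
CSV/JSON artifact; figures are illustrations only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .breath_analysis import VentilationSequence, analyze_episode
from .io import to_jsonable, write_breath_table, write_sequence_summaries
from .longitudinal import (bootstrap_dyncorr, build_panel,
                           chi_square_obstruction, dynamical_correlation,
                           fit_random_effects_panel, loess_trend, pearson_r,
                           summarize_median_iqr)
from .pairing import StudyGroups, assign_groups, pair_by_duration, pairs_to_frame
from .ventsim import StudyData, simulate_study

__all__ = ["RunConfig", "RunResult", "run_full_study"]

log = logging.getLogger("venticomp")

_PARAM_PAIRS = [("pip", "ev_t"), ("pip", "leak"), ("leak", "ev_t")]


@dataclass
class RunConfig:
    """Fully serialisable configuration of a study run."""

    seed: int = 1
    n_providers: int = 18
    set_pip: float = 30.0
    set_peep: float = 5.0
    gas_flow: float = 8.0
    pairing_tolerance: float = 0.15
    min_rise_mbar: float = 5.0
    flow_floor_ml_kg: float = 1.0
    loess_span: float = 0.5
    loess_min_subjects: int = 5
    n_bootstrap: int = 1000
    n_obstructed_manikin: int = 4
    n_obstructed_baby: int = 7
    make_figures: bool = True
    out_dir: str = "venticomp_run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory handles to everything a study run produced."""

    config: RunConfig
    study: StudyData
    manikin_sequences: list[VentilationSequence]
    baby_sequences: list[VentilationSequence]
    groups: StudyGroups
    panel: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    panel_tests: pd.DataFrame
    obstruction: dict
    out_dir: Path
    artifacts: dict[str, str] = field(default_factory=dict)


def _settings_from_config(config: RunConfig):
    from .ventsim import ResuscitatorSettings
    return ResuscitatorSettings(set_pip=config.set_pip,
                                set_peep=config.set_peep,
                                gas_flow=config.gas_flow)


def _stage(name: str, msg: str) -> None:
    log.info("[%s] %s", name, msg)


def run_full_study(config: RunConfig | None = None, **overrides) -> RunResult:
    """Run the complete synthetic study and write the report bundle.

    Stages: simulate (2 x n_providers manikin episodes + matched newborn
    pool), analyze (breath tables), pair (±15% PPV duration, consecutive
    allocation), group (MS/BS/ML/BL), stats (Table-1-style medians, panel
    comparisons, trends, correlations, obstruction chi-square). Outputs land
    under ``config.out_dir`` with a ``manifest.json`` recording the config
    hash and SHA-256 of every text artifact; a rerun with the same config
    reproduces them byte-identically.
    """
    if config is None:
        config = RunConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    _stage("simulate", f"{config.n_providers} providers, seed {config.seed}")
    settings = _settings_from_config(config)
    study = simulate_study(n_providers=config.n_providers, seed=config.seed,
                           settings=settings,
                           n_obstructed_manikin=config.n_obstructed_manikin,
                           n_obstructed_baby=config.n_obstructed_baby)
    _stage("simulate", f"{len(study.manikin_episodes)} manikin + "
                       f"{len(study.baby_episodes)} baby episodes")

    _stage("analyze", "extracting per-inflation parameters")
    m_seqs = [analyze_episode(ep, min_rise=config.min_rise_mbar,
                              flow_floor=config.flow_floor_ml_kg)
              for ep in study.manikin_episodes]
    b_seqs = [analyze_episode(ep, min_rise=config.min_rise_mbar,
                              flow_floor=config.flow_floor_ml_kg)
              for ep in study.baby_episodes]
    n_breaths = sum(s.n_breaths for s in m_seqs + b_seqs)
    _stage("analyze", f"{n_breaths} ventilations extracted")
    artifacts["breaths.csv"] = str(
        write_breath_table(m_seqs + b_seqs, out / "breaths.csv"))
    artifacts["sequences.json"] = str(
        write_sequence_summaries(m_seqs + b_seqs, out / "sequences.json"))

    _stage("pair", f"tolerance ±{config.pairing_tolerance:.0%}")
    pairs = pair_by_duration(m_seqs, b_seqs,
                             tolerance=config.pairing_tolerance)
    pdf = pairs_to_frame(pairs)
    pdf.to_csv(out / "pairs.csv", index=False, float_format="%.6g")
    artifacts["pairs.csv"] = str(out / "pairs.csv")
    groups = assign_groups(pairs, m_seqs, b_seqs)
    sizes = groups.sizes()
    _stage("pair", f"group sizes {sizes}")
    (out / "groups.json").write_text(json.dumps(
        {g: [s.episode_id for s in seqs] for g, seqs in groups.groups.items()},
        indent=2))
    artifacts["groups.json"] = str(out / "groups.json")

    _stage("stats", "building panel and summaries")
    panel = build_panel(groups)
    table1 = summarize_median_iqr(panel)
    table1.to_csv(out / "table1.csv", index=False, float_format="%.6g")
    artifacts["table1.csv"] = str(out / "table1.csv")

    rows = []
    for cls in ("S", "L"):
        for param in ("pip", "peep", "ev_t", "leak"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_random_effects_panel(panel, param,
                                               duration_class=cls)
            rows.append({"duration_class": cls, "parameter": param,
                         "contrast": fit.contrast_label,
                         "coef": fit.coef, "se": fit.se,
                         "p_value": fit.p_value, "method": fit.method,
                         "nw_lag": fit.nw_lag})
    panel_tests = pd.DataFrame(rows)
    panel_tests.to_csv(out / "panel_tests.csv", index=False,
                       float_format="%.6g")
    artifacts["panel_tests.csv"] = str(out / "panel_tests.csv")

    _stage("stats", f"dynamical correlations ({config.n_bootstrap} bootstrap)")
    t2_rows = []
    boot_seed = (config.seed * 9973 + 17) % (2 ** 31)
    for gi, (g, cls) in enumerate([("M", "S"), ("B", "S"),
                                   ("M", "L"), ("B", "L")]):
        for pi, (px, py) in enumerate(_PARAM_PAIRS):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    dc = bootstrap_dyncorr(panel, px, py, group=g,
                                           duration_class=cls,
                                           n_boot=config.n_bootstrap,
                                           seed=boot_seed + 10 * gi + pi)
                except ValueError:
                    # fewer than 5 subjects: point estimate, no bootstrap
                    dc = dynamical_correlation(panel, px, py, group=g,
                                               duration_class=cls)
                r, _ = pearson_r(panel, px, py, group=g, duration_class=cls)
            t2_rows.append({"group": g + cls, "pair": f"{px}-{py}",
                            "dyn_rho": dc.rho, "ci_low": dc.ci_low,
                            "ci_high": dc.ci_high, "p_value": dc.p_value,
                            "pearson_r": r})
    table2 = pd.DataFrame(t2_rows)
    table2.to_csv(out / "table2.csv", index=False, float_format="%.6g")
    artifacts["table2.csv"] = str(out / "table2.csv")

    _stage("stats", "LOESS trend curves")
    for g in ("M", "B"):
        for cls in ("S", "L"):
            for param in ("pip", "peep", "ev_t", "leak"):
                try:
                    tc = loess_trend(panel, param, group=g,
                                     duration_class=cls,
                                     span=config.loess_span,
                                     min_subjects=config.loess_min_subjects)
                except ValueError:
                    continue
                name = f"trend_{g}{cls}_{param}.csv"
                tc.to_frame().to_csv(out / name, index=False,
                                     float_format="%.6g")
                artifacts[name] = str(out / name)

    n_obs_m = sum(1 for s in m_seqs if s.obstructed)
    n_obs_b = sum(1 for s in b_seqs if s.obstructed)
    try:
        chi2, p_chi = chi_square_obstruction(n_obs_m, len(m_seqs),
                                             n_obs_b, len(b_seqs))
    except ValueError:  # degenerate margin at very small scale
        chi2, p_chi = float("nan"), float("nan")
    obstruction = {"n_obstructed_manikin": n_obs_m,
                   "n_manikin": len(m_seqs),
                   "n_obstructed_baby": n_obs_b,
                   "n_baby": len(b_seqs),
                   "chi_square": chi2, "p_value": p_chi}
    (out / "obstruction.json").write_text(
        json.dumps(to_jsonable(obstruction), indent=2))
    artifacts["obstruction.json"] = str(out / "obstruction.json")
    _stage("stats", f"obstruction {n_obs_m}/{len(m_seqs)} vs "
                    f"{n_obs_b}/{len(b_seqs)}, chi2={chi2:.3f} p={p_chi:.3f}")

    if config.make_figures:
        _stage("figures", "box plots, trends, scatter plots")
        _make_figures(panel, out)

    config.to_yaml(out / "config.yaml")
    manifest = {
        "package": "venticomp",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "group_sizes": sizes,
        "n_ventilations": int(n_breaths),
        "artifacts": {name: _sha256(Path(p)) for name, p in artifacts.items()},
    }
    (out / "manifest.json").write_text(json.dumps(to_jsonable(manifest),
                                                  indent=2))
    _stage("done", f"report bundle in {out}")
    return RunResult(config=config, study=study, manikin_sequences=m_seqs,
                     baby_sequences=b_seqs, groups=groups, panel=panel,
                     table1=table1, table2=table2, panel_tests=panel_tests,
                     obstruction=obstruction, out_dir=out,
                     artifacts=artifacts)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _make_figures(panel: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    order = [("M", "S"), ("B", "S"), ("M", "L"), ("B", "L")]
    labels = [g + c for g, c in order]
    units = {"pip": "mbar", "peep": "mbar", "ev_t": "mL/kg", "leak": "%"}
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.5))
    for ax, param in zip(axes, ("pip", "peep", "ev_t", "leak")):
        data = [panel.loc[(panel.parameter == param) & (panel.group == g)
                          & (panel.duration_class == c), "value"].dropna()
                for g, c in order]
        ax.boxplot(data, tick_labels=labels, showfliers=False)
        ax.set_title(param)
        ax.set_ylabel(units[param])
    fig.tight_layout()
    fig.savefig(fig_dir / "boxplots.png", dpi=110)
    plt.close(fig)

    from .longitudinal import loess_trend
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.5))
    for ax, param in zip(axes, ("pip", "peep", "ev_t", "leak")):
        for g, c in order:
            try:
                tc = loess_trend(panel, param, group=g, duration_class=c)
            except ValueError:
                continue
            ax.plot(tc.breath_index, tc.smoothed_mean, label=g + c)
            ax.fill_between(tc.breath_index,
                            tc.smoothed_mean - tc.standard_error,
                            tc.smoothed_mean + tc.standard_error, alpha=0.2)
        ax.set_title(param)
        ax.set_xlabel("breath index")
    if axes[0].get_legend_handles_labels()[1]:
        axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(fig_dir / "trends.png", dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for row, g in enumerate(("M", "B")):
        wide = panel[panel.group == g].pivot_table(
            index=["subject_id", "breath_index"], columns="parameter",
            values="value")
        for col, (px, py) in enumerate(_PARAM_PAIRS):
            ax = axes[row][col]
            sub = wide[[px, py]].dropna()
            ax.scatter(sub[px], sub[py], s=4, alpha=0.3)
            ax.set_xlabel(px)
            ax.set_ylabel(py)
            ax.set_title(f"{g}: {px} vs {py}", fontsize=9)
    fig.tight_layout()
    fig.savefig(fig_dir / "scatter.png", dpi=110)
    plt.close(fig)
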