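"""End-to-end analysis runs: configuration, outputs, manifests.

`run_analysis` ties the Bayesian and classical maps together for a pair of
trajectory files and writes cluster tables (CSV), a JSON manifest that is
sufficient to reproduce the run, and optional summary plots.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import PRIOR_SCALES, PriorSpec, resolve_scale
from .data import TrajectorySet, read_trajectories
from .ppm import PosteriorProbabilityMap, bayesian_spm, extract_clusters
from .rft import SPMtResult, spm_t_test

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis",
           "bayes_cluster_table", "classical_cluster_table"]

CLUSTER_COLUMNS = ["dataset", "design", "null_type", "r_label", "hypothesis",
                   "rule", "start_node", "end_node", "start_pct", "end_pct",
                   "extremum"]


def _r_label(r: float) -> str:
    for name, value in PRIOR_SCALES.items():
        if abs(r - value) < 1e-12:
            return name
    return f"{r:g}"


@dataclass
class AnalysisConfig:
    """Configuration of one paired/two-sample analysis run."""

    design: str = "paired"
    null_type: str = "interval"
    r: float | str = "medium"
    c: float = 0.2
    prior_odds: float = 1.0
    alpha: float = 0.05
    pp_threshold: float = 0.95
    q_threshold: float = 0.05
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self):
        self.r = resolve_scale(self.r)
        if self.design not in ("paired", "two_sample"):
            raise ValueError(f"design must be paired|two_sample, got {self.design!r}")
        if self.null_type not in ("point", "interval"):
            raise ValueError(f"null_type must be point|interval, got {self.null_type!r}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if self.null_type == "interval" and self.c == 0:
            raise ValueError("interval null requires c > 0")
        if not self.prior_odds > 0:
            raise ValueError(f"prior_odds must be positive, got {self.prior_odds}")
        for name in ("alpha", "pp_threshold", "q_threshold"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {value}")

    @property
    def prior(self) -> PriorSpec:
        return PriorSpec(r=self.r, c=self.c, prior_odds=self.prior_odds)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["r_label"] = _r_label(self.r)
        return d


@dataclass
class AnalysisResult:
    """Bundle of one run: posterior map, classical result, cluster tables."""

    config: AnalysisConfig
    ppm: PosteriorProbabilityMap
    spm: SPMtResult
    bayes_clusters: pd.DataFrame
    classical_clusters: pd.DataFrame
    manifest: dict


def bayes_cluster_table(pmap: PosteriorProbabilityMap, dataset: str,
                        pp_threshold: float = 0.95,
                        q_threshold: float = 0.05) -> pd.DataFrame:
    """Cluster table for both hypotheses under both threshold rules."""
    rows = []
    for hypothesis in ("H0", "H1"):
        for rule in ("pp_095", "q_005"):
            clusters = extract_clusters(pmap, hypothesis, rule,
                                        pp_threshold=pp_threshold,
                                        q_threshold=q_threshold)
            for cl in clusters:
                rows.append({
                    "dataset": dataset, "design": pmap.design,
                    "null_type": pmap.null_type,
                    "r_label": _r_label(pmap.prior.r),
                    "hypothesis": hypothesis, "rule": rule,
                    "start_node": cl.start_node, "end_node": cl.end_node,
                    "start_pct": cl.start_pct, "end_pct": cl.end_pct,
                    "extremum": cl.extremum,
                })
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def classical_cluster_table(spm: SPMtResult, dataset: str,
                            design: str) -> pd.DataFrame:
    rows = [{
        "dataset": dataset, "design": design, "null_type": "point",
        "r_label": "", "hypothesis": "H1", "rule": f"rft_{spm.alpha:g}",
        "start_node": cl.start_node, "end_node": cl.end_node,
        "start_pct": cl.start_pct, "end_pct": cl.end_pct,
        "extremum": cl.extremum, "p_value": cl.p_value,
    } for cl in spm.clusters]
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS + ["p_value"])


def run_analysis(config: AnalysisConfig, input_a, input_b,
                 label: str | None = None,
                 make_plots: bool = False) -> AnalysisResult:
    """Run the Bayesian and classical SPM analyses on two trajectory files
    (or TrajectorySet objects) and write cluster CSVs plus a JSON manifest
    into ``config.output_dir``."""
    a = input_a if isinstance(input_a, TrajectorySet) else read_trajectories(input_a)
    b = input_b if isinstance(input_b, TrajectorySet) else read_trajectories(input_b)
    dataset = label or f"{a.label}_vs_{b.label}"

    pmap = bayesian_spm(a, b, config.design, config.prior,
                        null_type=config.null_type, label=dataset)
    spm = spm_t_test(a, b, config.design, alpha=config.alpha)

    bayes_df = bayes_cluster_table(pmap, dataset, config.pp_threshold,
                                   config.q_threshold)
    classical_df = classical_cluster_table(spm, dataset, config.design)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bayes_path = out / f"{dataset}_bayes_clusters.csv"
    classical_path = out / f"{dataset}_classical_clusters.csv"
    bayes_df.to_csv(bayes_path, index=False, float_format="%.10g")
    classical_df.to_csv(classical_path, index=False, float_format="%.10g")

    import scipy

    manifest = {
        "dataset": dataset,
        "inputs": {"a": str(input_a), "b": str(input_b),
                   "shape_a": list(a.values.shape),
                   "shape_b": list(b.values.shape)},
        "config": config.to_dict(),
        "classical": {"fwhm": spm.fwhm, "resel_count": spm.resel_count,
                      "t_star": spm.t_star, "n_clusters": len(spm.clusters)},
        "versions": {"bspm": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
        "outputs": {"bayes_clusters": bayes_path.name,
                    "classical_clusters": classical_path.name},
    }
    with open(out / f"{dataset}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if make_plots:
        _write_plots(a, b, pmap, spm, out / f"{dataset}_panels.png", config)

    return AnalysisResult(config=config, ppm=pmap, spm=spm,
                          bayes_clusters=bayes_df,
                          classical_clusters=classical_df,
                          manifest=manifest)


def _write_plots(a, b, pmap, spm, path, config):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct = a.pct
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.4))
    ax = axes[0]
    for tset, color in ((a, "C0"), (b, "C1")):
        m, s = tset.mean(), tset.sd()
        ax.plot(pct, m, color=color, label=tset.label or None)
        ax.fill_between(pct, m - s, m + s, color=color, alpha=0.25)
    ax.set_xlabel("% movement time")
    ax.set_title("mean ± 1 SD")
    if a.label or b.label:
        ax.legend(frameon=False, fontsize=8)

    ax = axes[1]
    ax.plot(pct, pmap.pp_h1, "k")
    ax.axhline(config.pp_threshold, ls="--", c="0.4")
    ax.axhline(1 - config.pp_threshold, ls="--", c="0.4")
    ax.set_ylim(0, 1)
    ax.set_xlabel("% movement time")
    ax.set_title("P(H1 | data)")

    ax = axes[2]
    masked = np.where(np.minimum(pmap.q_h1, pmap.q_h0) <= config.q_threshold,
                      pmap.pp_h1, np.nan)
    ax.plot(pct, pmap.pp_h1, color="0.8")
    ax.plot(pct, masked, "r")
    ax.set_ylim(0, 1)
    ax.set_xlabel("% movement time")
    ax.set_title(f"q <= {config.q_threshold:g} thresholded PPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
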