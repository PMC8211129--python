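"""Posterior probability maps over a 1D field.

A Bayes factor is computed independently at every node of the registered
time axis and converted to posterior probabilities, giving a posterior
probability map (PPM).  Discovery control across the field uses the false
discovery rate: either the conservative rule PP >= 0.95 (FDR <= 0.05 by
construction) or the q-value rule, where the q-value at a node is the
cumulative mean of the posterior error probabilities (PEP = 1 - PP of the
claimed hypothesis) taken in ascending PEP order -- the minimal FDR
threshold at which that node enters a supra-threshold cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import (PriorSpec, TStatistic, bf_to_posterior, jzs_bf_interval,
                    jzs_bf_point)
from .data import TrajectorySet, node_to_pct

__all__ = [
    "DegenerateNodeError",
    "TStatisticField",
    "PosteriorProbabilityMap",
    "Cluster",
    "ClusterSet",
    "t_statistic_field",
    "bayesian_spm",
    "q_values",
    "extract_clusters",
]

DESIGNS = ("paired", "two_sample")


class DegenerateNodeError(ValueError):
    """Raised when a node has zero variance, making t undefined there."""

    def __init__(self, node: int):
        self.node = node  # 1-based
        super().__init__(f"zero variance at node {node}; t statistic undefined")


@dataclass(frozen=True)
class TStatisticField:
    """Nodewise t statistics sharing one design (dof, effective n)."""

    values: np.ndarray
    dof: float
    effective_n: float

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        for v in self.values:
            yield TStatistic(value=float(v), dof=self.dof,
                             effective_n=self.effective_n)

    def __getitem__(self, i) -> TStatistic:
        return TStatistic(value=float(self.values[i]), dof=self.dof,
                          effective_n=self.effective_n)


def t_statistic_field(a: TrajectorySet, b: TrajectorySet,
                      design: str = "paired") -> TStatisticField:
    """Nodewise t statistics for a paired or (pooled-variance) two-sample
    design.

    Paired: t = mean(d)/(sd(d)/sqrt(J)) on the trialwise differences,
    nu = J - 1.  Two-sample: pooled-variance t, nu = n1 + n2 - 2, effective
    n = n1*n2/(n1+n2).
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}, got {design!r}")
    if a.n_nodes != b.n_nodes:
        raise ValueError(
            f"node counts differ: {a.n_nodes} vs {b.n_nodes}"
        )
    if design == "paired":
        if a.n_trials != b.n_trials:
            raise ValueError(
                "paired design requires equal trial counts, got "
                f"{a.n_trials} vs {b.n_trials}"
            )
        d = a.values - b.values
        j = d.shape[0]
        if j < 2:
            raise ValueError("paired design needs at least 2 pairs")
        sd = d.std(axis=0, ddof=1)
        t = _safe_t(d.mean(axis=0), sd / np.sqrt(j))
        return TStatisticField(values=t, dof=float(j - 1), effective_n=float(j))

    n1, n2 = a.n_trials, b.n_trials
    if n1 < 2 or n2 < 2:
        raise ValueError("two-sample design needs at least 2 trials per group")
    v1 = a.values.var(axis=0, ddof=1)
    v2 = b.values.var(axis=0, ddof=1)
    nu = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / nu
    diff = a.values.mean(axis=0) - b.values.mean(axis=0)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = _safe_t(diff, se)
    n_eff = n1 * n2 / (n1 + n2)
    return TStatisticField(values=t, dof=float(nu), effective_n=float(n_eff))


def _safe_t(diff: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Nodewise t = diff/se; zero variance with a zero difference (e.g.
    identical inputs) is taken as t = 0, zero variance with a nonzero
    difference is a genuine degeneracy and raises."""
    zero = se == 0
    if zero.any():
        bad = zero & (diff != 0)
        if bad.any():
            raise DegenerateNodeError(int(np.argmax(bad)) + 1)
        t = np.zeros_like(diff)
        ok = ~zero
        t[ok] = diff[ok] / se[ok]
        return t
    return diff / se


def q_values(pep: np.ndarray) -> np.ndarray:
    """q-values from posterior error probabilities.

    Nodes are ranked by PEP ascending; the q at rank k is the mean of the
    k smallest PEPs, mapped back to the original node order.  Tied PEPs
    all receive the cumulative mean at their last tied rank, which makes
    the result independent of how the sort breaks ties.
    """
    pep = np.asarray(pep, dtype=float)
    if pep.ndim != 1:
        raise ValueError("pep must be 1-D")
    if ((pep < 0) | (pep > 1)).any():
        raise ValueError("pep values must lie in [0, 1]")
    s = np.sort(pep)
    cum = np.cumsum(s) / np.arange(1, len(s) + 1)
    # last tied rank for each node's PEP value
    last = np.searchsorted(s, pep, side="right") - 1
    return cum[last]


@dataclass(frozen=True)
class PosteriorProbabilityMap:
    """Nodewise Bayesian SPM: Bayes factors, posterior probabilities,
    posterior error probabilities and q-values for both hypotheses."""

    bf10: np.ndarray
    pp_h1: np.ndarray
    pp_h0: np.ndarray
    pep_h1: np.ndarray
    pep_h0: np.ndarray
    q_h1: np.ndarray
    q_h0: np.ndarray
    prior: PriorSpec
    design: str
    null_type: str
    label: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.bf10)

    def pp(self, hypothesis: str) -> np.ndarray:
        return self.pp_h1 if hypothesis == "H1" else self.pp_h0

    def pep(self, hypothesis: str) -> np.ndarray:
        return self.pep_h1 if hypothesis == "H1" else self.pep_h0

    def q(self, hypothesis: str) -> np.ndarray:
        return self.q_h1 if hypothesis == "H1" else self.q_h0


def bayesian_spm(a: TrajectorySet, b: TrajectorySet, design: str,
                 prior: PriorSpec, null_type: str = "interval",
                 label: str = "") -> PosteriorProbabilityMap:
    """Bayesian SPM: posterior probability map over the field.

    Applies the point- or interval-null JZS Bayes factor test at every
    node, converts to posterior probabilities with the prior odds in
    ``prior``, and fills in PEPs and q-values for both hypotheses.
    """
    if null_type not in ("point", "interval"):
        raise ValueError(f"null_type must be 'point' or 'interval', got {null_type!r}")
    tf = t_statistic_field(a, b, design)
    bf_fn = jzs_bf_point if null_type == "point" else jzs_bf_interval
    bf10 = np.empty(len(tf))
    pp_h1 = np.empty(len(tf))
    for i, t in enumerate(tf):
        res = bf_fn(t, prior)
        bf10[i] = res.bf10
        pp_h1[i] = bf_to_posterior(res.bf10, prior.prior_odds).pp_h1
    pp_h0 = 1.0 - pp_h1
    pep_h1 = pp_h0  # error probability of claiming H1
    pep_h0 = pp_h1
    return PosteriorProbabilityMap(
        bf10=bf10, pp_h1=pp_h1, pp_h0=pp_h0,
        pep_h1=pep_h1, pep_h0=pep_h0,
        q_h1=q_values(pep_h1), q_h0=q_values(pep_h0),
        prior=prior, design=design, null_type=null_type,
        label=label or f"{a.label} vs {b.label}",
    )


@dataclass(frozen=True)
class Cluster:
    """A maximal contiguous run of nodes passing a threshold rule.

    Node indices are 1-based inclusive; percent positions assume the field
    spans 0-100% of movement time.
    """

    start_node: int
    end_node: int
    start_pct: float
    end_pct: float
    hypothesis: str
    threshold_rule: str
    extremum: float

    @property
    def extent_nodes(self) -> int:
        return self.end_node - self.start_node + 1


class ClusterSet(list):
    """List of clusters; for the q rule, ``max_admitted_pep`` records the
    largest posterior error probability among admitted nodes."""

    def __init__(self, clusters=(), max_admitted_pep: float | None = None):
        super().__init__(clusters)
        self.max_admitted_pep = max_admitted_pep


def _runs(mask: np.ndarray):
    """Maximal runs of True, as (start, end) 0-based inclusive pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts, ends))


def extract_clusters(pmap: PosteriorProbabilityMap, hypothesis: str = "H1",
                     rule: str = "pp_095", pp_threshold: float = 0.95,
                     q_threshold: float = 0.05) -> ClusterSet:
    """Supra-threshold clusters of a posterior probability map.

    ``rule='pp_095'`` keeps nodes with PP(hypothesis) >= ``pp_threshold``;
    ``rule='q_005'`` keeps nodes with q(hypothesis) <= ``q_threshold``.
    Clusters are reported 1-based inclusive and in percent of movement
    time; the extremum is the max PP (pp rule) or min q (q rule) inside
    the cluster.
    """
    if hypothesis not in ("H0", "H1"):
        raise ValueError(f"hypothesis must be 'H0' or 'H1', got {hypothesis!r}")
    if rule not in ("pp_095", "q_005"):
        raise ValueError(f"rule must be 'pp_095' or 'q_005', got {rule!r}")
    q = pmap.n_nodes
    if rule == "pp_095":
        values = pmap.pp(hypothesis)
        mask = values >= pp_threshold
        pick = np.max
        max_pep = None
    else:
        values = pmap.q(hypothesis)
        mask = values <= q_threshold
        pick = np.min
        max_pep = float(pmap.pep(hypothesis)[mask].max()) if mask.any() else None
    clusters = [
        Cluster(
            start_node=int(s + 1), end_node=int(e + 1),
            start_pct=node_to_pct(s + 1, q), end_pct=node_to_pct(e + 1, q),
            hypothesis=hypothesis, threshold_rule=rule,
            extremum=float(pick(values[s:e + 1])),
        )
        for s, e in _runs(mask)
    ]
    return ClusterSet(clusters, max_admitted_pep=max_pep)
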