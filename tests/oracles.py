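"""Brute-force integration oracles for the JZS Bayes factor.

These deliberately avoid the package's computational route: the Bayes
factor is written as a marginal over the effect size delta (noncentral-t
likelihood times Cauchy prior) and integrated with dense trapezoid sums
on grids whose edges align exactly with the truncation points, so that
no region-splitting error is introduced at |delta| = c.
"""

import math

import numpy as np
from scipy import stats


def _integrand(delta, t, dof, n_eff, r):
    sqrt_n = math.sqrt(n_eff)
    return stats.nct.pdf(t, dof, delta * sqrt_n) * stats.cauchy.pdf(delta, scale=r)


def _half_width(t, n_eff, r):
    return max(15.0, 15.0 * abs(t) / math.sqrt(n_eff)) * max(r, 1.0)


def bf_point_grid(t, dof, n_eff, r, n_points=400001):
    """Point-null BF10 by dense Riemann (trapezoid) integration over delta."""
    center = t / math.sqrt(n_eff)
    half = _half_width(t, n_eff, r)
    d = np.linspace(center - half, center + half, n_points)
    num = np.trapezoid(_integrand(d, t, dof, n_eff, r), d)
    return num / stats.t.pdf(t, dof)


def bf_interval_grid(t, dof, n_eff, r, c, n_points=200001):
    """Interval-null BF10 as the ratio of the two truncated-prior marginal
    likelihoods, each integrated on its own c-aligned dense grid."""
    half = _half_width(t, n_eff, r) + abs(t) / math.sqrt(n_eff)
    d_in = np.linspace(-c, c, n_points)
    m_in = np.trapezoid(_integrand(d_in, t, dof, n_eff, r), d_in)
    d_lo = np.linspace(-half, -c, n_points)
    d_hi = np.linspace(c, half, n_points)
    m_out = (np.trapezoid(_integrand(d_lo, t, dof, n_eff, r), d_lo)
             + np.trapezoid(_integrand(d_hi, t, dof, n_eff, r), d_hi))
    prior_in = (math.atan2(c, r) - math.atan2(-c, r)) / math.pi
    return (m_out / (1.0 - prior_in)) / (m_in / prior_in)
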