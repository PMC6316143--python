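"""Molecular-clock likelihood-ratio test for 4-taxon loci.

Each locus is fit twice under the same substitution model: a free-rates
unrooted tree ((Homo,Pan),Gorilla,Pongo) with 5 branch lengths, and a
strict-clock rooted ultrametric tree (((Homo,Pan),Gorilla),Pongo) with 3
node heights (Pongo is the outgroup).  Twice the log-likelihood difference
is referred to chi-square with 2 degrees of freedom (5 - 3 free
parameters), and loci with p >= alpha are kept: the filter retains loci
that fail to reject the clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .simulate import LocusAlignment
from .substitution import SubstitutionModel, jc69_distance_from_mismatch

CLOCK_DF = 2
_TAXA_ORDER = ("Homo", "Pan", "Gorilla", "Pongo")
_MAX_BRANCH = 3.0
_MIN_BRANCH = 0.0


@dataclass
class ClockTestResult:
    """Per-locus outcome of the clock-vs-free likelihood ratio test."""

    locus_id: str
    lnl_free: float
    lnl_clock: float
    lr: float
    df: int
    p_value: float
    keep: bool


# ---------------------------------------------------------------------------
# site-pattern compression and pruning likelihood
# ---------------------------------------------------------------------------

def site_patterns(alignment: LocusAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Compress an alignment into unique site patterns and counts.

    Rows of the returned pattern array follow Homo, Pan, Gorilla, Pongo
    order regardless of the order in the file.
    """
    if alignment.length == 0:
        raise ValueError("zero-length alignment")
    try:
        order = [alignment.taxa.index(t) for t in _TAXA_ORDER]
    except ValueError as exc:
        raise ValueError(f"alignment must contain taxa {_TAXA_ORDER}") from exc
    codes = alignment.codes[order]
    packed = (
        codes[0].astype(np.int32) * 64
        + codes[1] * 16
        + codes[2] * 4
        + codes[3]
    )
    ids, counts = np.unique(packed, return_counts=True)
    patterns = np.stack([ids // 64, (ids // 16) % 4, (ids // 4) % 4, ids % 4])
    return patterns.astype(np.intp), counts.astype(np.float64)


def _pattern_loglik(
    patterns: np.ndarray,
    counts: np.ndarray,
    model: SubstitutionModel,
    branches: dict[str, float],
) -> float:
    """Felsenstein pruning on the rooted shape (((H,P),G),O).

    ``branches`` gives tip-to-parent and internal branch lengths: keys
    homo, pan, gorilla, pongo, hc (HC node to HCG node) and hcg (HCG node
    to root).  Any unrooted 4-taxon tree with the (H,P) split is covered by
    setting hcg = 0 and folding its length into pongo (valid under model
    reversibility).
    """
    rates, weights = model.site_rate_mixture()
    pi = np.asarray(model.base_freqs)
    site_lik = np.zeros(patterns.shape[1])
    for rate, weight in zip(rates, weights):
        p_h = model.transition_matrix(branches["homo"] * rate)
        p_p = model.transition_matrix(branches["pan"] * rate)
        p_g = model.transition_matrix(branches["gorilla"] * rate)
        p_o = model.transition_matrix(branches["pongo"] * rate)
        p_hc = model.transition_matrix(branches["hc"] * rate)
        p_hcg = model.transition_matrix(branches["hcg"] * rate)
        # tip partials are one-hot: select matrix columns by observed base
        hc_partial = p_h[:, patterns[0]] * p_p[:, patterns[1]]        # (4, n_pat)
        hcg_partial = (p_hc @ hc_partial) * p_g[:, patterns[2]]
        root_partial = (p_hcg @ hcg_partial) * p_o[:, patterns[3]]
        site_lik += weight * (pi @ root_partial)
    site_lik = np.maximum(site_lik, 1e-300)
    return float(counts @ np.log(site_lik))


def loglikelihood(
    alignment: LocusAlignment,
    branches: dict[str, float],
    model: SubstitutionModel,
) -> float:
    """Log-likelihood of a branch-length assignment for one locus."""
    patterns, counts = site_patterns(alignment)
    return _pattern_loglik(patterns, counts, model, branches)


# ---------------------------------------------------------------------------
# maximum-likelihood fits
# ---------------------------------------------------------------------------

def _distance_init(patterns: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Start free branch lengths from pairwise JC69 distances."""
    total = counts.sum()

    def dist(i: int, j: int) -> float:
        p = counts[patterns[i] != patterns[j]].sum() / total
        d = jc69_distance_from_mismatch(min(p, 0.70))
        return max(d, 1e-6)

    d_hp = dist(0, 1)
    d_hg, d_pg = dist(0, 2), dist(1, 2)
    d_ho, d_po, d_go = dist(0, 3), dist(1, 3), dist(2, 3)
    b_h = max((d_hp + d_hg - d_pg) / 2, 1e-6)
    b_p = max(d_hp - b_h, 1e-6)
    # internal + gorilla + pongo from average external distances
    b_g = max((d_hg + d_pg) / 2 - (b_h + b_p) / 2, 1e-6) / 2
    b_o = max((d_ho + d_po) / 2 - (b_h + b_p) / 2, 1e-6) / 2
    b_i = max(((d_hg + d_pg + d_ho + d_po) / 4 - (b_h + b_p) / 2 - d_go / 2), 1e-6)
    return np.array([b_h, b_p, b_i, b_g, b_o])


def _optimize(fun, x0_list, bounds):
    best = None
    for x0 in x0_list:
        res = minimize(
            fun,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        # ties within tolerance resolved toward smaller total tree length
        if (
            best is None
            or res.fun < best.fun - 1e-8
            or (abs(res.fun - best.fun) <= 1e-8 and res.x.sum() < best.x.sum())
        ):
            best = res
    return best


def fit_free(
    alignment: LocusAlignment,
    model: SubstitutionModel,
    n_restarts: int = 2,
    seed: int = 0,
    extra_inits: list[np.ndarray] | None = None,
) -> tuple[dict[str, float], float]:
    """ML fit of the 5 branch lengths of the unrooted tree ((H,P),G,O).

    Starts from a distance-based configuration plus random restarts to guard
    against local optima.
    """
    patterns, counts = site_patterns(alignment)
    rng = np.random.default_rng(seed)

    def negloglik(x: np.ndarray) -> float:
        b = {
            "homo": x[0], "pan": x[1], "hc": x[2],
            "gorilla": x[3], "pongo": x[4], "hcg": 0.0,
        }
        return -_pattern_loglik(patterns, counts, model, b)

    init = _distance_init(patterns, counts)
    inits = [init] + list(extra_inits or [])
    inits += [init * rng.uniform(0.25, 4.0, size=5) for _ in range(n_restarts)]
    bounds = [(_MIN_BRANCH, _MAX_BRANCH)] * 5
    res = _optimize(negloglik, inits, bounds)
    names = ("homo", "pan", "hc", "gorilla", "pongo")
    branches = dict(zip(names, (float(v) for v in res.x)))
    branches["hcg"] = 0.0
    return branches, -float(res.fun)


def fit_clock(
    alignment: LocusAlignment,
    model: SubstitutionModel,
    n_restarts: int = 2,
    seed: int = 0,
) -> tuple[dict[str, float], float]:
    """ML fit of the 3 node heights of the ultrametric tree (((H,P),G),O).

    Heights are parameterized as (h_hc, h_hcg - h_hc, h_root - h_hcg), all
    bounded below by 0, which enforces 0 <= h_hc <= h_hcg <= h_root.
    """
    patterns, counts = site_patterns(alignment)
    rng = np.random.default_rng(seed)

    def negloglik(x: np.ndarray) -> float:
        h1, h2, h3 = x[0], x[0] + x[1], x[0] + x[1] + x[2]
        b = {
            "homo": h1, "pan": h1, "hc": h2 - h1,
            "gorilla": h2, "hcg": h3 - h2, "pongo": h3,
        }
        return -_pattern_loglik(patterns, counts, model, b)

    d0 = _distance_init(patterns, counts)
    h1 = (d0[0] + d0[1]) / 2
    init = np.array([h1, max(d0[2], 1e-6), max(d0[3] - h1, 1e-6)])
    inits = [init] + [init * rng.uniform(0.25, 4.0, size=3) for _ in range(n_restarts)]
    bounds = [(_MIN_BRANCH, _MAX_BRANCH)] * 3
    res = _optimize(negloglik, inits, bounds)
    h_hc = float(res.x[0])
    h_hcg = h_hc + float(res.x[1])
    h_root = h_hcg + float(res.x[2])
    heights = {"hc": h_hc, "hcg": h_hcg, "root": h_root}
    return heights, -float(res.fun)


def lrt(
    alignment: LocusAlignment,
    model: SubstitutionModel,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClockTestResult:
    """Clock-vs-free LRT for one locus: keep when p >= alpha.

    The free fit is additionally started from the clock solution so the
    nesting inequality lnL_free >= lnL_clock holds numerically.
    """
    heights, lnl_clock = fit_clock(alignment, model, seed=seed)
    clock_as_free = np.array([
        heights["hc"],
        heights["hc"],
        max(heights["hcg"] - heights["hc"], _MIN_BRANCH),
        heights["hcg"],
        2 * heights["root"] - heights["hcg"],  # pongo path through the root
    ])
    _, lnl_free = fit_free(alignment, model, seed=seed, extra_inits=[clock_as_free])
    lnl_free = max(lnl_free, lnl_clock)  # clamp optimizer jitter on nested fits
    lr = 2.0 * (lnl_free - lnl_clock)
    p = float(chi2.sf(lr, CLOCK_DF))
    return ClockTestResult(
        locus_id=alignment.locus_id,
        lnl_free=lnl_free,
        lnl_clock=lnl_clock,
        lr=lr,
        df=CLOCK_DF,
        p_value=p,
        keep=p >= alpha,
    )


def filter_loci(
    loci: list[LocusAlignment],
    model: SubstitutionModel,
    alpha: float = 0.05,
    report_path: str | Path | None = None,
) -> tuple[list[LocusAlignment], pd.DataFrame]:
    """Run the clock LRT on every locus and keep those with p >= alpha."""
    rows = []
    kept = []
    for aln in loci:
        result = lrt(aln, model, alpha=alpha)
        rows.append(
            {
                "locus_id": result.locus_id,
                "lnL_free": result.lnl_free,
                "lnL_clock": result.lnl_clock,
                "LR": result.lr,
                "df": result.df,
                "p": result.p_value,
                "keep": result.keep,
            }
        )
        if result.keep:
            kept.append(aln)
    report = pd.DataFrame(rows)
    if report_path is not None:
        report.to_csv(report_path, sep="\t", index=False)
    return kept, report
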