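"""Drift-diffusion modelling of two-alternative choice/RT data.

Implements the Wiener first-passage-time density (small/large-time series
expansions with automatic selection), Euler-Maruyama simulation, and a
hierarchical Bayesian fit in which every subject has a drift rate per
stimulus cluster (or one shared drift for the null model), a boundary
separation and a non-decision time, each drawn from group-level normals.
Responses are accuracy-coded: a correct response is an upper-boundary
crossing, the start point is fixed midway between the boundaries, and no
inter-trial variability parameters are modeled.

Model comparison uses the deviance information criterion (DIC); posterior
inference on drifts uses the overlap statistic P_p|D, the fraction of
paired posterior draws satisfying an ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._wiener import log_density_arr, simulate_paths
from .errors import InsufficientDataError, InvalidArgumentError

DENSITY_EPS = 1e-10


# ---------------------------------------------------------------------------
# parameters and datasets


@dataclass
class DDMParams:
    """Diffusion parameters: drift v (per condition or scalar), boundary
    separation a, non-decision time t, relative start point w."""

    v: float | Mapping[int, float]
    a: float
    t: float
    w: float = 0.5

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidArgumentError("boundary separation a must be > 0")
        if not 0 < self.w < 1:
            raise InvalidArgumentError("start point w must be in (0, 1)")
        if self.t < 0:
            raise InvalidArgumentError("non-decision time t must be >= 0")
        vs = self.v.values() if isinstance(self.v, Mapping) else [self.v]
        if not all(np.isfinite(list(vs))):
            raise InvalidArgumentError("drift rates must be finite")

    def drift(self, condition: int | None = None) -> float:
        if isinstance(self.v, Mapping):
            if condition not in self.v:
                raise InvalidArgumentError(f"no drift for condition "
                                           f"{condition!r}")
            return float(self.v[condition])
        return float(self.v)


@dataclass
class ChoiceRTDataset:
    """Observer decisions with RTs, keyed to the stimulus cluster.

    ``df`` columns: subject, stimulus, intent, cluster, response
    ('correct'/'error'), rt_s (seconds).
    """

    df: pd.DataFrame

    REQUIRED = ("subject", "cluster", "response", "rt_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise InvalidArgumentError(f"missing columns: {missing}")
        if (self.df["rt_s"] <= 0).any():
            raise InvalidArgumentError("all RTs must be positive")
        bad = ~self.df["response"].isin(["correct", "error"])
        if bad.any():
            raise InvalidArgumentError("response must be 'correct'/'error'")

    @property
    def clusters(self) -> list[int]:
        return sorted(self.df["cluster"].unique().tolist())

    @property
    def subjects(self) -> list:
        return sorted(self.df["subject"].unique().tolist())

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChoiceRTDataset":
        df = pd.read_csv(path)
        if "intent" in df.columns:  # empty labels round-trip as NaN
            df["intent"] = df["intent"].fillna("")
        return cls(df)


# ---------------------------------------------------------------------------
# density and simulation


_CHOICE_CODE = {"upper": 1, "lower": 0, "correct": 1, "error": 0, 1: 1, 0: 0}


def _code_choices(choice) -> np.ndarray:
    arr = np.asarray(choice)
    if arr.dtype.kind in "iub":
        return arr.astype(np.int64)
    return np.array([_CHOICE_CODE[c] for c in arr.ravel()],
                    dtype=np.int64).reshape(arr.shape)


def wiener_logpdf(rt, choice, v, a, t, w: float = 0.5,
                  eps: float = DENSITY_EPS) -> np.ndarray:
    """Log first-passage density; -inf where rt <= t (zero density)."""
    rt = np.atleast_1d(np.asarray(rt, dtype=float))
    ch = np.atleast_1d(_code_choices(choice))
    v, a, t = (np.broadcast_to(np.asarray(x, dtype=float), rt.shape).copy()
               for x in (v, a, t))
    ch = np.broadcast_to(ch, rt.shape).copy()
    return log_density_arr(rt, ch, v, a, t, float(w), eps)


def wiener_density(rt, choice, params: DDMParams,
                   condition: int | None = None,
                   eps: float = DENSITY_EPS) -> np.ndarray:
    """First-passage density of the diffusion at the given boundary."""
    v = params.drift(condition)
    return np.exp(wiener_logpdf(rt, choice, v, params.a, params.t,
                                params.w, eps))


def prob_upper(v: float, a: float, w: float = 0.5) -> float:
    """Probability of absorbing at the upper boundary (closed form)."""
    if a <= 0 or not 0 < w < 1:
        raise InvalidArgumentError("need a > 0 and 0 < w < 1")
    if abs(v) < 1e-12:
        return w
    num = 1.0 - math.exp(-2.0 * v * a * w)
    den = 1.0 - math.exp(-2.0 * v * a)
    return num / den


def simulate_ddm(params: DDMParams, n: int, seed: int,
                 dt: float = 1e-3, max_t: float = 10.0,
                 condition: int | None = None) -> pd.DataFrame:
    """Euler-Maruyama simulation of n first-passage trials.

    Returns a frame with columns rt, choice (1 upper / 0 lower) and
    censored (True for paths that never hit a boundary before max_t)."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if dt <= 0 or dt > 0.01:
        raise InvalidArgumentError("dt must be in (0, 0.01]")
    v = params.drift(condition)
    rt, choice = simulate_paths(v, params.a, params.t, params.w,
                                int(n), float(dt), float(max_t),
                                int(seed) % (2 ** 31))
    censored = choice < 0
    return pd.DataFrame({"rt": rt, "choice": choice, "censored": censored})


# ---------------------------------------------------------------------------
# hierarchical Bayesian fit


@dataclass
class MCMCConfig:
    """Sampler settings.  Proposal scales adapt during burn-in only."""

    n_iter: int = 1500
    burn: int = 500
    chains: int = 2
    seed: int = 0
    adapt_window: int = 25
    target_accept: float = 0.40


@dataclass
class Priors:
    """Weakly-informative group-level priors on the empirical RT scale."""

    mu_v_mean: float = 0.0
    mu_v_sd: float = 2.0
    mu_a_mean: float = 1.5
    mu_a_sd: float = 1.0
    mu_t_mean: float = 0.3
    mu_t_sd: float = 0.3
    sigma_scale: float = 1.0     # half-normal scale for group sds


@dataclass
class PosteriorSamples:
    """Retained MCMC draws of the group-level parameters.

    ``draws`` maps parameter name -> (chains, n_retained) array.  Subject-
    level posterior means are kept for the plug-in deviance used by DIC.
    """

    draws: dict[str, np.ndarray]
    deviance: np.ndarray                       # (chains, n_retained)
    subject_means: dict[str, np.ndarray]       # v_sc (S, C), a_s, t_s
    clusters: list[int]
    subjects: list
    drift_by_cluster: bool
    rhat: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_retained(self) -> int:
        return self.deviance.shape[1]

    def flat(self, name: str) -> np.ndarray:
        if name not in self.draws:
            raise InvalidArgumentError(f"unknown parameter {name!r}")
        return self.draws[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for name, arr in self.draws.items():
            cols[name] = arr.reshape(-1)
        out = pd.DataFrame(cols)
        chains, n = self.deviance.shape
        out["chain"] = np.repeat(np.arange(chains), n)
        out["deviance"] = self.deviance.reshape(-1)
        return out


def _split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor."""
    chains, n = x.shape
    half = n // 2
    segs = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, l = segs.shape
    means = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean()
    B = l * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (l - 1) / l * W + B / l
    return float(np.sqrt(var_plus / W))


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


class _HierState:
    """One chain's state for the Metropolis-within-Gibbs sampler."""

    def __init__(self, rt, choice, subj_idx, clus_idx, S, C, rng,
                 priors: Priors, w: float):
        self.rt, self.choice = rt, choice
        self.subj_idx, self.clus_idx = subj_idx, clus_idx
        self.S, self.C = S, C
        self.rng = rng
        self.priors = priors
        self.w = w
        self.cell = subj_idx * C + clus_idx
        self.n_cells = S * C
        # counts per cell/subject, for acceptance bookkeeping
        self.min_rt_s = np.full(S, np.inf)
        np.minimum.at(self.min_rt_s, subj_idx, rt)
        # initial values: crude moment-based starting points
        acc = np.zeros(self.n_cells)
        ncell = np.bincount(self.cell, minlength=self.n_cells)
        np.add.at(acc, self.cell, (choice == 1).astype(float))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.clip(np.where(ncell > 0, acc / np.maximum(ncell, 1), 0.5),
                        0.05, 0.95)
        self.v = (np.log(p / (1 - p))).reshape(S, C)
        self.a = np.full(S, 1.5)
        self.t = 0.5 * np.minimum(self.min_rt_s, 1.0)
        self.mu_v = self.v.mean(axis=0)
        self.sig_v = max(self.v.std(), 0.2)
        self.mu_a, self.sig_a = 1.5, 0.2
        self.mu_t, self.sig_t = float(np.mean(self.t)), 0.1
        # adaptive proposal scales
        self.sc_v = np.full((S, C), 0.3)
        self.sc_a = np.full(S, 0.15)
        self.sc_t = np.full(S, 0.05)
        self.sc_grp = {"sig_v": 0.3, "mu_a": 0.15, "sig_a": 0.3,
                       "mu_t": 0.05, "sig_t": 0.3}
        self.acc_v = np.zeros((S, C))
        self.acc_a = np.zeros(S)
        self.acc_t = np.zeros(S)
        self.acc_grp = {k: 0.0 for k in self.sc_grp}
        self.cell_ll = self._cell_ll(self.v, self.a, self.t)

    # -- likelihood helpers -------------------------------------------------
    def _trial_ll(self, v, a, t):
        vt = v.reshape(-1)[self.cell]
        at = a[self.subj_idx]
        tt = t[self.subj_idx]
        return log_density_arr(self.rt, self.choice, vt, at, tt,
                               self.w, DENSITY_EPS)

    def _cell_ll(self, v, a, t):
        ll = self._trial_ll(v, a, t)
        out = np.zeros(self.n_cells)
        np.add.at(out, self.cell, ll)
        return out.reshape(self.S, self.C)

    def total_ll(self) -> float:
        return float(self.cell_ll.sum())

    # -- update blocks ------------------------------------------------------
    def update_v(self):
        prop = self.v + self.sc_v * self.rng.standard_normal(self.v.shape)
        cell_prop = self._cell_ll(prop, self.a, self.t)
        logr = (cell_prop - self.cell_ll
                + _norm_logpdf(prop, self.mu_v[None, :], self.sig_v)
                - _norm_logpdf(self.v, self.mu_v[None, :], self.sig_v))
        accept = np.log(self.rng.random(self.v.shape)) < logr
        self.v = np.where(accept, prop, self.v)
        self.cell_ll = np.where(accept, cell_prop, self.cell_ll)
        self.acc_v += accept

    def _update_subject_block(self, cur, scale, acc, prior_mu, prior_sd,
                              lower, make_args):
        prop = cur + scale * self.rng.standard_normal(self.S)
        ok = prop > lower
        cell_prop = self._cell_ll(*make_args(np.where(ok, prop, cur)))
        subj_cur = self.cell_ll.sum(axis=1)
        subj_prop = cell_prop.sum(axis=1)
        logr = (subj_prop - subj_cur
                + _norm_logpdf(prop, prior_mu, prior_sd)
                - _norm_logpdf(cur, prior_mu, prior_sd))
        accept = ok & (np.log(self.rng.random(self.S)) < logr)
        new = np.where(accept, prop, cur)
        self.cell_ll = np.where(accept[:, None], cell_prop, self.cell_ll)
        acc += accept
        return new

    def update_a(self):
        self.a = self._update_subject_block(
            self.a, self.sc_a, self.acc_a, self.mu_a, self.sig_a, 0.0,
            lambda a: (self.v, a, self.t))

    def update_t(self):
        self.t = self._update_subject_block(
            self.t, self.sc_t, self.acc_t, self.mu_t, self.sig_t, 0.0,
            lambda t: (self.v, self.a, t))

    def _mh_group(self, name, cur, logpost):
        prop = cur + self.sc_grp[name] * self.rng.standard_normal()
        lp_cur = logpost(cur)
        lp_prop = logpost(prop)
        if np.log(self.rng.random()) < lp_prop - lp_cur:
            self.acc_grp[name] += 1
            return prop
        return cur

    def update_group(self):
        pr = self.priors
        # conjugate draw for each cluster-level mean drift
        prec = self.S / self.sig_v ** 2 + 1.0 / pr.mu_v_sd ** 2
        mean = (self.v.sum(axis=0) / self.sig_v ** 2
                + pr.mu_v_mean / pr.mu_v_sd ** 2) / prec
        self.mu_v = mean + self.rng.standard_normal(self.C) / np.sqrt(prec)

        def lp_sig(sig, values, mu):
            if sig <= 0:
                return -np.inf
            return (np.sum(_norm_logpdf(values, mu, sig))
                    - 0.5 * (sig / pr.sigma_scale) ** 2)

        self.sig_v = self._mh_group(
            "sig_v", self.sig_v,
            lambda s: lp_sig(s, self.v, self.mu_v[None, :]))
        self.mu_a = self._mh_group(
            "mu_a", self.mu_a,
            lambda m: (-np.inf if m <= 0 else
                       np.sum(_norm_logpdf(self.a, m, self.sig_a))
                       + _norm_logpdf(m, pr.mu_a_mean, pr.mu_a_sd)))
        self.sig_a = self._mh_group(
            "sig_a", self.sig_a, lambda s: lp_sig(s, self.a, self.mu_a))
        self.mu_t = self._mh_group(
            "mu_t", self.mu_t,
            lambda m: (-np.inf if m < 0 else
                       np.sum(_norm_logpdf(self.t, m, self.sig_t))
                       + _norm_logpdf(m, pr.mu_t_mean, pr.mu_t_sd)))
        self.sig_t = self._mh_group(
            "sig_t", self.sig_t, lambda s: lp_sig(s, self.t, self.mu_t))

    def adapt(self, window: int, target: float):
        def tune(scale, acc):
            rate = acc / window
            return np.clip(scale * np.exp(1.2 * (rate - target)),
                           1e-4, 10.0)
        self.sc_v = tune(self.sc_v, self.acc_v)
        self.sc_a = tune(self.sc_a, self.acc_a)
        self.sc_t = tune(self.sc_t, self.acc_t)
        for k in self.sc_grp:
            self.sc_grp[k] = float(tune(np.array(self.sc_grp[k]),
                                        np.array(self.acc_grp[k])))
            self.acc_grp[k] = 0.0
        self.acc_v[:] = 0.0
        self.acc_a[:] = 0.0
        self.acc_t[:] = 0.0


def fit_hierarchical(data: ChoiceRTDataset,
                     drift_by_cluster: bool = True,
                     mcmc: MCMCConfig | None = None,
                     priors: Priors | None = None,
                     w: float = 0.5) -> PosteriorSamples:
    """Fit the hierarchical diffusion model by Metropolis-within-Gibbs.

    Subject drifts v_{s,c} ~ N(mu_v_c, sig_v) (one shared mean when
    ``drift_by_cluster`` is false), boundaries a_s ~ N(mu_a, sig_a)
    constrained positive, non-decision times t_s ~ N(mu_t, sig_t)
    constrained non-negative.  Proposal scales adapt during burn-in only;
    the deviance -2 log L is recorded for every retained draw and split
    R-hat is reported per group parameter (fits with any R-hat above 1.1
    are flagged, not suppressed).
    """
    mcmc = mcmc or MCMCConfig()
    priors = priors or Priors()
    if mcmc.chains < 2:
        raise InvalidArgumentError("need >= 2 chains for convergence checks")
    df = data.df
    subjects = data.subjects
    clusters = data.clusters if drift_by_cluster else [0]
    S = len(subjects)
    subj_map = {s: i for i, s in enumerate(subjects)}
    subj_idx = df["subject"].map(subj_map).to_numpy()
    if drift_by_cluster:
        clus_map = {c: i for i, c in enumerate(clusters)}
        clus_idx = df["cluster"].map(clus_map).to_numpy()
    else:
        clus_idx = np.zeros(len(df), dtype=int)
    C = len(clusters)
    rt = df["rt_s"].to_numpy(dtype=float)
    choice = _code_choices(df["response"].to_numpy())

    n_keep = mcmc.n_iter - mcmc.burn
    if n_keep < 100:
        raise InvalidArgumentError("need at least 100 retained iterations")
    names = ([f"mu_v_{c}" for c in clusters] if drift_by_cluster
             else ["mu_v"])
    names += ["sig_v", "mu_a", "sig_a", "mu_t", "sig_t"]
    draws = {n: np.empty((mcmc.chains, n_keep)) for n in names}
    deviance = np.empty((mcmc.chains, n_keep))
    v_mean = np.zeros((S, C))
    a_mean = np.zeros(S)
    t_mean = np.zeros(S)

    for chain in range(mcmc.chains):
        rng = np.random.default_rng((mcmc.seed, chain))
        state = _HierState(rt, choice, subj_idx, clus_idx, S, C, rng,
                           priors, w)
        kept = 0
        for it in range(mcmc.n_iter):
            state.update_v()
            state.update_a()
            state.update_t()
            state.update_group()
            if it < mcmc.burn:
                if (it + 1) % mcmc.adapt_window == 0:
                    state.adapt(mcmc.adapt_window, mcmc.target_accept)
                continue
            for ci, c in enumerate(clusters):
                key = f"mu_v_{c}" if drift_by_cluster else "mu_v"
                draws[key][chain, kept] = state.mu_v[ci]
            draws["sig_v"][chain, kept] = state.sig_v
            draws["mu_a"][chain, kept] = state.mu_a
            draws["sig_a"][chain, kept] = state.sig_a
            draws["mu_t"][chain, kept] = state.mu_t
            draws["sig_t"][chain, kept] = state.sig_t
            deviance[chain, kept] = -2.0 * state.total_ll()
            v_mean += state.v
            a_mean += state.a
            t_mean += state.t
            kept += 1
    total = mcmc.chains * n_keep
    rhat = {n: _split_rhat(draws[n]) for n in names}
    converged = all(r < 1.1 for r in rhat.values())
    return PosteriorSamples(
        draws=draws, deviance=deviance,
        subject_means={"v": v_mean / total, "a": a_mean / total,
                       "t": t_mean / total},
        clusters=clusters, subjects=subjects,
        drift_by_cluster=drift_by_cluster, rhat=rhat, converged=converged)


# ---------------------------------------------------------------------------
# model comparison and posterior tests


def dic(samples: PosteriorSamples, data: ChoiceRTDataset) -> float:
    """DIC = mean deviance + pD, pD = mean deviance - deviance at the
    posterior mean of the subject-level parameters."""
    if samples.n_retained * samples.deviance.shape[0] < 100:
        raise InsufficientDataError("fewer than 100 retained draws")
    df = data.df
    subj_map = {s: i for i, s in enumerate(samples.subjects)}
    subj_idx = df["subject"].map(subj_map).to_numpy()
    if samples.drift_by_cluster:
        clus_map = {c: i for i, c in enumerate(samples.clusters)}
        clus_idx = df["cluster"].map(clus_map).to_numpy()
    else:
        clus_idx = np.zeros(len(df), dtype=int)
    C = len(samples.clusters)
    cell = subj_idx * C + clus_idx
    v = samples.subject_means["v"].reshape(-1)[cell]
    a = samples.subject_means["a"][subj_idx]
    t = samples.subject_means["t"][subj_idx]
    rt = df["rt_s"].to_numpy(dtype=float)
    choice = _code_choices(df["response"].to_numpy())
    ll = log_density_arr(rt, choice, v, a, t, 0.5, DENSITY_EPS)
    d_hat = -2.0 * float(ll.sum())
    d_bar = float(samples.deviance.mean())
    p_d = d_bar - d_hat
    return d_bar + p_d


@dataclass
class ModelComparison:
    dic_cluster: float
    dic_null: float
    margin: float = 10.0
    delta: float = field(init=False)
    preferred: str = field(init=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dic_cluster) and np.isfinite(self.dic_null)):
            raise InvalidArgumentError("DIC values must be finite")
        self.delta = self.dic_null - self.dic_cluster
        if self.delta > self.margin:
            self.preferred = "cluster"
        elif self.delta < -self.margin:
            self.preferred = "null"
        else:
            self.preferred = "inconclusive"


def compare_models(dic_cluster: float, dic_null: float,
                   margin: float = 10.0) -> ModelComparison:
    """Prefer the lower-DIC model when the difference exceeds the margin."""
    return ModelComparison(dic_cluster, dic_null, margin)


@dataclass
class OverlapResult:
    comparison: tuple[str, str | float]
    p_overlap: float          # P_p|D(A < B)
    significant: bool


def posterior_overlap(samples: PosteriorSamples, param_a: str,
                      param_b: str | float = 0.0,
                      criterion: float = 0.05) -> OverlapResult:
    """P_p|D(A < B): fraction of paired draws with the A-draw below the
    B-draw (or below a constant).  Significant when the overlap falls
    outside [criterion, 1 - criterion]."""
    a = samples.flat(param_a)
    if isinstance(param_b, str):
        b = samples.flat(param_b)
    else:
        b = float(param_b)
    p = float(np.mean(a < b))
    return OverlapResult(comparison=(param_a, param_b), p_overlap=p,
                         significant=(p < criterion) or (p > 1 - criterion))
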