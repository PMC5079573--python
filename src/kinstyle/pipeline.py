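"""End-to-end orchestration of the execution and observation analyses.

The execution analysis mirrors the motor study: select session-2 trials,
extract kinematic features, cluster per intent and summarize cluster
shares, predictor importance and within-participant style consistency.
The observation analysis fits the cluster and null diffusion models to
observer choice/RT data, compares them by DIC and runs the posterior
overlap tests.  Both emit machine-readable JSON reports (plus CSVs and a
posterior-density figure) and are deterministic given the configuration
and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ddm as ddm_mod
from . import kinfeat, stimselect, stylecluster, synthkin
from .errors import InvalidArgumentError, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    seed: int = 0
    outdir: str | None = None
    # synthetic execution study
    n_participants: int = 17
    style_groups: dict = field(
        default_factory=lambda: {"pour": 3, "drink": 3, "place": 2})
    separation: float = 6.0
    noise_sd: float = synthkin.DEFAULT_NOISE_SD
    trials_per_intent_per_session: int = 10
    # feature extraction
    cutoff_hz: float = kinfeat.DEFAULT_CUTOFF_HZ
    threshold_mm_s: float = kinfeat.DEFAULT_THRESHOLD_MM_S
    n_points: int = kinfeat.DEFAULT_N_POINTS
    # clustering
    k_max: int = stylecluster.DEFAULT_K_MAX
    bic_ratio: float = stylecluster.DEFAULT_BIC_RATIO
    # stimulus selection
    select_pair: tuple = ("pour", "drink")
    n_select: int = 50
    # observation study
    true_drifts: dict = field(
        default_factory=lambda: {1: 0.2, 2: 1.0, 3: 1.2})
    true_a: float = 1.5
    true_t: float = 0.3
    n_observers: int = 18
    obs_trials_per_cell: int = 100
    mcmc_iter: int = 1500
    mcmc_burn: int = 500
    mcmc_chains: int = 2

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.seed < 0:
            raise InvalidArgumentError("seed must be non-negative")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def style_consistency(assignments: pd.DataFrame) -> dict:
    """Count trials falling outside their participant's modal cluster.

    ``assignments`` columns: participant, intent, cluster.  Returns the
    total trial count, the number of misassigned trials and the breakdown
    per intent.
    """
    mis_by_intent = {}
    total = 0
    mis = 0
    for intent, grp in assignments.groupby("intent"):
        m = 0
        for _, part in grp.groupby("participant"):
            modal = part["cluster"].mode().iloc[0]
            m += int((part["cluster"] != modal).sum())
        mis_by_intent[intent] = m
        mis += m
        total += len(grp)
    return {"n_trials": total, "n_misassigned": mis,
            "by_intent": mis_by_intent}


def run_execution_analysis(config: RunConfig,
                           trials: list | None = None,
                           truth: synthkin.GroundTruth | None = None
                           ) -> dict:
    """Cluster session-2 trials per intent and summarize movement styles.

    When no trials are passed, a synthetic dataset is generated from the
    configuration.  Returns a report with, per intent: retained trial
    count, selected number of clusters, cluster shares (%), top predictor
    variables, and the overall style-consistency count; plus the trial
    assignments and (when ground truth is known) the adjusted Rand index.
    """
    if trials is None:
        profiles, truth = synthkin.gen_styles(
            config.n_participants, config.style_groups, config.separation,
            seed=config.seed, noise_sd=config.noise_sd)
        trials = synthkin.gen_dataset(
            profiles, config.trials_per_intent_per_session,
            sessions=(1, 2), seed=config.seed + 1)
    session2 = [t for t in trials if t.session == 2]
    if not session2:
        raise InvalidArgumentError("no session-2 trials found")
    intents = sorted({t.intent for t in session2})
    per_intent = {}
    assign_rows = []
    models = {}
    for intent in intents:
        sub = [t for t in session2 if t.intent == intent]
        fm = kinfeat.build_feature_matrix(
            sub, cutoff_hz=config.cutoff_hz,
            threshold_mm_s=config.threshold_mm_s, n_points=config.n_points)
        model = stylecluster.fit_two_step(
            fm, k_max=config.k_max, ratio_criterion=config.bic_ratio)
        models[intent] = (fm, model)
        shares = model.shares()
        entry = {
            "n_trials": fm.n_trials,
            "n_dropped": len(fm.dropped),
            "k": model.k,
            "cluster_shares_pct": [round(float(s), 2) for s in shares],
        }
        if not model.importances.empty:
            top = stylecluster.importance_by_variable(model.importances)
            entry["top_variables"] = top.head(4).index.tolist()
        if truth is not None and intent in truth.style_assignments:
            true_lab = fm.meta["participant"].map(
                truth.style_assignments[intent]).to_numpy()
            entry["ari"] = round(
                adjusted_rand_index(true_lab, model.assignments), 4)
        per_intent[intent] = entry
        for tid, part, clus in zip(fm.meta["trial_id"],
                                   fm.meta["participant"],
                                   model.assignments):
            assign_rows.append({"trial_id": tid, "participant": part,
                                "intent": intent, "cluster": int(clus)})
    assignments = pd.DataFrame(assign_rows)
    report = {
        "per_intent": per_intent,
        "style_consistency": style_consistency(assignments),
        "config": config.to_dict(),
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        assignments.to_csv(out / "assignments.csv", index=False)
        for intent, (fm, model) in models.items():
            if not model.importances.empty:
                model.importances.to_csv(out / f"importances_{intent}.csv")
        _write_json(report, out / "execution_report.json")
    report["_assignments"] = assignments
    report["_models"] = models
    return report


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (contingency form)."""
    a = pd.Categorical(np.asarray(labels_a)).codes
    b = pd.Categorical(np.asarray(labels_b)).codes
    n = len(a)
    if n != len(b):
        raise InvalidArgumentError("labelings must have equal length")
    cont = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def run_observation_analysis(config: RunConfig,
                             data: ddm_mod.ChoiceRTDataset | None = None
                             ) -> dict:
    """Fit cluster and null diffusion models and test drift differences.

    When no dataset is passed, observer data are simulated from the true
    diffusion parameters in the configuration.  The report carries both
    DICs, their difference and the preferred model, drift posterior means,
    pairwise cluster overlap probabilities and drift-vs-zero overlaps with
    the 5% significance flags, and the per-parameter split R-hats.
    """
    if data is None:
        truth = synthkin.GroundTruth(
            style_assignments={},
            ddm_params=ddm_mod.DDMParams(
                v=dict(config.true_drifts), a=config.true_a, t=config.true_t))
        data = synthkin.gen_observer_data(
            truth, config.obs_trials_per_cell, config.n_observers,
            seed=config.seed + 2)
    counts = data.df.groupby("cluster").size()
    if (counts == 0).any() or len(counts) == 0:
        raise InvalidArgumentError("every cluster needs at least one trial")
    mcmc = ddm_mod.MCMCConfig(n_iter=config.mcmc_iter, burn=config.mcmc_burn,
                              chains=config.mcmc_chains, seed=config.seed)
    fit_c = ddm_mod.fit_hierarchical(data, drift_by_cluster=True, mcmc=mcmc)
    fit_0 = ddm_mod.fit_hierarchical(data, drift_by_cluster=False, mcmc=mcmc)
    dic_c = ddm_mod.dic(fit_c, data)
    dic_0 = ddm_mod.dic(fit_0, data)
    comparison = ddm_mod.compare_models(dic_c, dic_0)
    clusters = fit_c.clusters
    overlaps = {}
    for i, ca in enumerate(clusters):
        for cb in clusters[i + 1:]:
            res = ddm_mod.posterior_overlap(fit_c, f"mu_v_{cb}",
                                            f"mu_v_{ca}")
            overlaps[f"cluster{cb}<cluster{ca}"] = {
                "p_overlap": res.p_overlap, "significant": res.significant}
    vs_zero = {}
    for c in clusters:
        res = ddm_mod.posterior_overlap(fit_c, f"mu_v_{c}", 0.0)
        vs_zero[f"cluster{c}<0"] = {
            "p_overlap": res.p_overlap, "significant": res.significant}
    drift_means = {f"cluster{c}": float(fit_c.flat(f"mu_v_{c}").mean())
                   for c in clusters}
    report = {
        "dic_cluster": dic_c,
        "dic_null": dic_0,
        "delta_dic": comparison.delta,
        "preferred": comparison.preferred,
        "drift_posterior_means": drift_means,
        "pairwise_overlaps": overlaps,
        "drift_vs_zero": vs_zero,
        "rhat_cluster_model": fit_c.rhat,
        "converged": fit_c.converged and fit_0.converged,
        "config": config.to_dict(),
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        fit_c.to_frame().to_csv(out / "posterior_draws_cluster.csv",
                                index=False)
        _write_json(report, out / "observation_report.json")
        _plot_posteriors(fit_c, out / "drift_posteriors.png")
    report["_fit_cluster"] = fit_c
    report["_fit_null"] = fit_0
    return report


def _plot_posteriors(samples: ddm_mod.PosteriorSamples, path: Path) -> None:
    """Posterior density figure for the per-cluster group drifts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    fig, ax = plt.subplots(figsize=(6, 4))
    for c in samples.clusters:
        draws = samples.flat(f"mu_v_{c}")
        kde = sps.gaussian_kde(draws)
        grid = np.linspace(draws.min() - 0.3, draws.max() + 0.3, 300)
        ax.plot(grid, kde(grid), label=f"cluster {c}")
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("group drift rate v (evidence/s)")
    ax.set_ylabel("posterior density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_stimulus_selection(config: RunConfig, execution_report: dict) -> dict:
    """LDA-based representative-movement selection on clustered trials."""
    pair = tuple(config.select_pair)
    models = execution_report["_models"]
    for intent in pair:
        if intent not in models:
            raise InvalidArgumentError(f"intent {intent!r} not clustered")
    fms = {i: models[i][0] for i in pair}
    X = np.vstack([fms[i].X for i in pair])
    intents = np.concatenate([[i] * fms[i].n_trials for i in pair])
    ids = np.concatenate([fms[i].meta["trial_id"].to_numpy() for i in pair])
    lda = stimselect.fit_lda(X, intents)
    n_avail = min(int((intents == i).sum()) for i in pair)
    n_sel = min(config.n_select, n_avail)
    selection = stimselect.select_representatives(
        lda, X, intents, trial_ids=ids, n_select=n_sel)
    profile = stimselect.cluster_profile(
        selection, execution_report["_assignments"])
    report = {
        "pair": list(pair),
        "n_selected_per_intent": {i: len(v) for i, v in selection.items()},
        "profile": profile.drop(columns="movements_per_actor")
                          .to_dict(orient="records"),
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [{"intent": i, "trial_id": t}
                for i, ts in selection.items() for t in ts]
        pd.DataFrame(rows).to_csv(out / "selection.csv", index=False)
        profile.to_csv(out / "selection_profile.csv", index=False)
        _write_json(report, out / "selection_report.json")
    report["_selection"] = selection
    report["_profile"] = profile
    return report


# ---------------------------------------------------------------------------
# deposited-workbook reader

_TRAJECTORY_COLS = {"trial_id", "participant", "intent", "session",
                    "time_s", "marker", "x", "y", "z"}
_CHOICE_COLS = {"subject", "cluster", "response", "rt_s"}


def read_deposited_dataset(path, sheet_map: dict | None = None) -> dict:
    """Read a deposited XLSX workbook into typed records.

    Sheet layouts are auto-detected from column names: a long-format
    trajectory sheet yields marker trials, a choice/RT sheet yields a
    :class:`~kinstyle.ddm.ChoiceRTDataset`, and a sheet whose columns look
    like ``variable@percent`` yields a feature table.  ``sheet_map`` can
    force a kind per sheet name ({'Sheet1': 'trajectories' | 'choice_rt' |
    'features'}).  Unrecognized sheets raise a schema error naming the
    columns found.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"workbook not found: {path}")
    book = pd.read_excel(path, sheet_name=None)
    if not book:
        raise SchemaError("workbook has no sheets")
    out: dict = {"trials": [], "choice_rt": None, "features": None,
                 "log": []}
    for name, df in book.items():
        cols = {str(c).strip().lower() for c in df.columns}
        df.columns = [str(c).strip().lower() for c in df.columns]
        kind = (sheet_map or {}).get(name)
        if kind is None:
            if _TRAJECTORY_COLS <= cols:
                kind = "trajectories"
            elif _CHOICE_COLS <= cols:
                kind = "choice_rt"
            elif any("@" in c for c in cols):
                kind = "features"
        if kind == "trajectories":
            before = df["trial_id"].nunique()
            df = df.dropna(subset=["x", "y", "z"])
            out["trials"].extend(synthkin.frame_to_trials(df))
            out["log"].append(f"{name}: {before} trials read")
        elif kind == "choice_rt":
            n0 = len(df)
            df = df.dropna(subset=list(_CHOICE_COLS))
            df = df[df["rt_s"] > 0]
            if len(df) < n0:
                out["log"].append(f"{name}: dropped {n0 - len(df)} rows")
            out["choice_rt"] = ddm_mod.ChoiceRTDataset(df.reset_index(drop=True))
        elif kind == "features":
            out["features"] = df
        else:
            raise SchemaError(
                f"sheet {name!r} has unrecognized layout; columns found: "
                f"{sorted(cols)}")
    return out
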