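"""Model fitting, convergence diagnostics and PSIS-LOO scoring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd

from ..design import ResponseTable
from .model import PriorConfig, SliderModel
from .nuts import NutsConfig, sample_nuts

__all__ = [
    "McmcConfig",
    "ModelConfig",
    "PosteriorDraws",
    "FitDiagnostics",
    "LooResult",
    "fit_model",
    "fit_joint",
    "diagnose",
    "compute_loo",
]


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings (defaults: 4 chains, short runs; see `paper_scale`)."""

    chains: int = 4
    warmup: int = 500
    draws: int = 500
    thin: int = 1
    target_accept: float = 0.95
    max_treedepth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least two chains are required")
        if self.draws < 1 or self.thin < 1:
            raise ValueError("draws and thin must be positive")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcConfig":
        """The published sampler settings for the joint model
        (4 chains x 6,000 kept iterations, thin 4, 2,000 warmup)."""
        return cls(chains=4, warmup=2000, draws=1500, thin=4, target_accept=0.95, seed=seed)


@dataclass(frozen=True)
class ModelConfig:
    invariance_level: str = "strict"
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)


@dataclass
class PosteriorDraws:
    """Posterior draws of the hierarchical model, indexed (chain, draw, ...).

    ``person`` holds the latent person matrix (chain, draw, P, d) with
    dimension labels in ``dim_labels``; ``corr`` the correlation-matrix
    draws; ``items`` the natural-scale item parameter arrays keyed by
    name with group labels in ``item_keys``.  ``log_lik`` (optional) has
    one column per response record, in table row order.
    """

    person: np.ndarray
    corr: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    items: dict[str, np.ndarray]
    item_keys: dict[str, list]
    dim_labels: list[str]
    person_ids: list[str]
    sample_stats: dict[str, np.ndarray]
    record_meta: pd.DataFrame
    invariance_level: str
    log_lik: np.ndarray | None = None
    diagnostics: "FitDiagnostics | None" = None

    @property
    def n_chains(self) -> int:
        return self.person.shape[0]

    @property
    def n_draws(self) -> int:
        return self.person.shape[1]

    def dim_index(self, label: str) -> int:
        return self.dim_labels.index(label)

    def corr_draws(self, label_a: str, label_b: str) -> np.ndarray:
        """Flattened posterior draws of one correlation entry."""
        i, j = self.dim_index(label_a), self.dim_index(label_b)
        return self.corr[..., i, j].reshape(-1)

    def _posterior_dict(self, include_person: bool = True) -> dict[str, np.ndarray]:
        """Non-degenerate parameters only (constants break Rhat)."""
        d = self.corr.shape[-1]
        il = np.tril_indices(d, k=-1)
        out: dict[str, np.ndarray] = {
            "corr_tril": self.corr[..., il[0], il[1]],
        }
        if include_person:
            out["person"] = self.person
        free = [k for k in range(d) if not np.allclose(self.sigma[..., k], 1.0)]
        if free:
            out["mu_free"] = self.mu[..., free]
            out["sigma_free"] = self.sigma[..., free]
        for name, arr in self.items.items():
            if arr.shape[-1]:
                out[name] = arr
        return out

    def to_inferencedata(self) -> az.InferenceData:
        groups: dict = {"posterior": self._posterior_dict()}
        if self.sample_stats:
            groups["sample_stats"] = self.sample_stats
        if self.log_lik is not None:
            groups["log_likelihood"] = {"obs": self.log_lik}
        return az.from_dict(**groups)

    def save(self, path) -> None:
        """Persist to an .npz archive (text-free, self-describing)."""
        payload = {
            "person": self.person,
            "corr": self.corr,
            "mu": self.mu,
            "sigma": self.sigma,
            "dim_labels": np.array(self.dim_labels),
            "person_ids": np.array(self.person_ids),
            "invariance_level": np.array(self.invariance_level),
        }
        for k, v in self.items.items():
            payload[f"item_{k}"] = v
        for k, v in self.sample_stats.items():
            payload[f"stat_{k}"] = v
        if self.log_lik is not None:
            payload["log_lik"] = self.log_lik
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as z:
            items = {
                k[len("item_") :]: z[k] for k in z.files if k.startswith("item_")
            }
            stats = {k[len("stat_") :]: z[k] for k in z.files if k.startswith("stat_")}
            return cls(
                person=z["person"],
                corr=z["corr"],
                mu=z["mu"],
                sigma=z["sigma"],
                items=items,
                item_keys={k: [] for k in items},
                dim_labels=list(z["dim_labels"]),
                person_ids=list(z["person_ids"]),
                sample_stats=stats,
                record_meta=pd.DataFrame(),
                invariance_level=str(z["invariance_level"]),
                log_lik=z["log_lik"] if "log_lik" in z.files else None,
            )


@dataclass
class FitDiagnostics:
    """Split-Rhat / ESS summary with pass/fail against thresholds."""

    rhat_max: float
    ess_bulk_min: float
    ess_tail_min: float
    divergences: int
    rhat_threshold: float
    ess_threshold: float
    per_parameter: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (
            np.isfinite(self.rhat_max)
            and self.rhat_max < self.rhat_threshold
            and self.ess_bulk_min >= self.ess_threshold
            and self.ess_tail_min >= self.ess_threshold
        )


@dataclass
class LooResult:
    """PSIS leave-one-out score: elpd, its SE, effective parameters, and
    the per-observation elpd vector used for model comparisons."""

    elpd_loo: float
    se: float
    p_loo: float
    n: int
    pareto_k: np.ndarray
    elpd_i: np.ndarray


# ---------------------------------------------------------------------------


def fit_model(
    table: ResponseTable,
    cfg: ModelConfig | None = None,
    invariance_level: str | None = None,
    store_loglik: bool = True,
    check_convergence: bool = True,
    diagnose_person: bool = True,
) -> PosteriorDraws:
    """Fit the hierarchical model to a (possibly restricted) table.

    Runs `cfg.mcmc.chains` sequential NUTS chains.  Deterministic for a
    fixed seed and data on a single machine.  If convergence diagnostics
    fail the result is flagged (``diagnostics.passed`` False and a
    warning), never silently discarded.
    """
    cfg = cfg or ModelConfig()
    level = invariance_level or cfg.invariance_level
    model = SliderModel(table, invariance_level=level, priors=cfg.priors)
    mc = cfg.mcmc
    nuts_cfg = NutsConfig(
        warmup=mc.warmup,
        draws=mc.draws,
        thin=mc.thin,
        target_accept=mc.target_accept,
        max_treedepth=mc.max_treedepth,
    )
    seeds = np.random.SeedSequence(mc.seed).spawn(mc.chains)
    C, S = mc.chains, mc.draws
    person = np.empty((C, S, model.P, model.d))
    corr = np.empty((C, S, model.d, model.d))
    mu = np.empty((C, S, model.d))
    sigma = np.empty((C, S, model.d))
    item_names = [
        "brm_alpha", "brm_delta", "brm_tau",
        "ddrm_alpha_loc", "ddrm_alpha_wid",
        "ddrm_delta_loc", "ddrm_delta_wid", "ddrm_tau",
    ]
    items: dict[str, np.ndarray] = {}
    log_lik = np.empty((C, S, model.n_records)) if store_loglik else None
    stats_all: dict[str, list] = {}

    for c in range(C):
        rng = np.random.default_rng(seeds[c])
        q0 = model.initial_value(rng)
        draws, stats = sample_nuts(
            model.logp_grad, q0, nuts_cfg, rng, inv_mass0=model.metric_init()
        )
        for s in range(S):
            snap = model.unpack(draws[s])
            person[c, s] = snap["person"]
            corr[c, s] = snap["corr"]
            mu[c, s] = snap["mu"]
            sigma[c, s] = snap["sigma"]
            for name in item_names:
                if name not in items:
                    items[name] = np.empty((C, S, len(snap[name])))
                items[name][c, s] = snap[name]
            if store_loglik:
                log_lik[c, s] = model.pointwise_loglik(draws[s])
        for k, v in stats.items():
            stats_all.setdefault(k, []).append(v)

    item_keys = {
        "brm_alpha": model.brm_alpha_keys,
        "brm_delta": model.brm_delta_keys,
        "brm_tau": model.brm_tau_keys,
        "ddrm_alpha_loc": model.ddrm_alpha_keys,
        "ddrm_alpha_wid": model.ddrm_alpha_keys,
        "ddrm_delta_loc": model.ddrm_delta_keys,
        "ddrm_delta_wid": model.ddrm_delta_keys,
        "ddrm_tau": model.ddrm_tau_keys,
    }
    result = PosteriorDraws(
        person=person,
        corr=corr,
        mu=mu,
        sigma=sigma,
        items=items,
        item_keys=item_keys,
        dim_labels=list(model.dim_labels),
        person_ids=list(model.persons),
        sample_stats={k: np.stack(v) for k, v in stats_all.items()},
        record_meta=table.df[["person_id", "item_id", "trait", "occasion", "format"]].copy(),
        invariance_level=level,
        log_lik=log_lik,
    )
    if check_convergence:
        result.diagnostics = diagnose(result, include_person=diagnose_person)
        if not result.diagnostics.passed:
            warnings.warn(
                f"sampler diagnostics failed (max Rhat {result.diagnostics.rhat_max:.3f}, "
                f"min bulk ESS {result.diagnostics.ess_bulk_min:.0f}, "
                f"min tail ESS {result.diagnostics.ess_tail_min:.0f}); "
                "inspect before using the draws",
                stacklevel=2,
            )
    return result


def fit_joint(table: ResponseTable, cfg: ModelConfig | None = None, **kw) -> PosteriorDraws:
    """Fit the joint model (all traits and formats) under strict invariance."""
    return fit_model(table, cfg, **kw)


def diagnose(
    draws: PosteriorDraws,
    rhat_max: float = 1.01,
    ess_min: float = 400.0,
    include_person: bool = True,
) -> FitDiagnostics:
    """Rank-normalised split-Rhat and bulk/tail ESS for every parameter.

    ``include_person=False`` restricts the check to the structural
    parameters (correlations, means/SDs, item parameters), which is much
    cheaper for flagging purposes.
    """
    if draws.n_chains < 2:
        raise ValueError("Rhat requires at least two chains")
    post = draws._posterior_dict(include_person=include_person)
    # constants (e.g. fixed identification parameters) have undefined Rhat
    post = {k: v for k, v in post.items() if np.ptp(v) > 0}
    if not post:
        raise ValueError("no varying parameters to diagnose")
    idata = az.from_dict(posterior=post)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess_bulk = az.ess(idata, method="bulk")
        ess_tail = az.ess(idata, method="tail")
    rmax = float(np.nanmax([np.nanmax(v) for v in rhat.data_vars.values()]))
    bmin = float(np.nanmin([np.nanmin(v) for v in ess_bulk.data_vars.values()]))
    tmin = float(np.nanmin([np.nanmin(v) for v in ess_tail.data_vars.values()]))
    div = int(draws.sample_stats.get("diverging", np.zeros(1)).sum())
    per_param = {
        "rhat": rhat,
        "ess_bulk": ess_bulk,
        "ess_tail": ess_tail,
    }
    return FitDiagnostics(
        rhat_max=rmax,
        ess_bulk_min=bmin,
        ess_tail_min=tmin,
        divergences=div,
        rhat_threshold=rhat_max,
        ess_threshold=ess_min,
        per_parameter=per_param,
    )


def compute_loo(draws: PosteriorDraws | np.ndarray) -> LooResult:
    """PSIS-smoothed leave-one-out expected log predictive density.

    Accepts a fitted :class:`PosteriorDraws` with stored pointwise
    log-likelihood, or a raw (chain, draw, observation) array.
    """
    if isinstance(draws, PosteriorDraws):
        if draws.log_lik is None:
            raise ValueError("fit was run without pointwise log-likelihood storage")
        ll = draws.log_lik
    else:
        ll = np.asarray(draws)
        if ll.ndim != 3:
            raise ValueError("log-likelihood array must be (chain, draw, observation)")
    # arviz requires a posterior group to locate chain/draw dims
    idata = az.from_dict(
        posterior={"_placeholder": np.zeros(ll.shape[:2])},
        log_likelihood={"obs": ll},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    return LooResult(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        p_loo=float(res.p_loo),
        n=ll.shape[2],
        pareto_k=np.asarray(res.pareto_k),
        elpd_i=np.asarray(res.loo_i),
    )
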