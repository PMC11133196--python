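"""Synthetic multitrait-multimethod datasets.

Generates complete studies with the statistical structure the analysis
assumes: person parameters drawn from a multivariate normal with a
configurable correlation matrix, one shared item-parameter set per item
(strict measurement invariance by construction), and responses drawn
from the same beta/Dirichlet measurement densities used by the fitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.special import expit

from .design import BLOCK_ORDERS, DRS, VAS, DesignSpec, ResponseTable
from .layout import PARAMS, latent_labels
from .models import BrmItemParams, DdrmItemParams

__all__ = [
    "ItemPrior",
    "PopulationConfig",
    "ItemPair",
    "TrueParams",
    "draw_persons",
    "draw_items",
    "simulate_study",
    "paper_like_population",
    "nearest_positive_definite",
]


@dataclass(frozen=True)
class ItemPrior:
    """Hyperparameters for drawing item parameters.

    Scalings are log-normal, difficulties normal, precisions log-normal;
    the same hyperparameters govern the location and width submodels of
    DRS items unless ``delta_wid_mu`` shifts the width difficulties.
    """

    alpha_logmu: float = 0.0
    alpha_logsd: float = 0.5
    delta_mu: float = 0.0
    delta_sd: float = 1.0
    tau_logmu: float = math.log(10.0)
    tau_logsd: float = 1.0
    delta_wid_mu: float = 0.0


@dataclass(frozen=True)
class PopulationConfig:
    """Population distribution of the latent person vector.

    The first-occasion block of means is fixed at zero and of SDs at
    one (the identification constraints of the fitted model); remaining
    entries are free.  ``R`` must be a valid correlation matrix.
    """

    mu: np.ndarray
    sigma: np.ndarray
    R: np.ndarray
    item_prior: ItemPrior = field(default_factory=ItemPrior)
    rounding: bool = False
    seed: int = 0
    dim_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "R", R)
        d = len(mu)
        if sigma.shape != (d,) or R.shape != (d, d):
            raise ValueError("mu, sigma, R dimensions disagree")
        if np.any(sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("R must be symmetric with unit diagonal")
        half = d // 2
        if not (np.all(mu[:half] == 0.0) and np.all(sigma[:half] == 1.0)):
            raise ValueError(
                "first-occasion block must have means fixed at 0 and SDs at 1"
            )

    @property
    def n_dims(self) -> int:
        return len(self.mu)


class ItemPair(NamedTuple):
    """Both parameter sets of one item (it is VAS for some persons, DRS for others)."""

    brm: BrmItemParams
    ddrm: DdrmItemParams


@dataclass(frozen=True)
class TrueParams:
    """Generating parameter values, for recovery scoring.

    ``persons`` rows follow ``dim_labels`` (occasion-major ordering, see
    :mod:`sliderirt.layout`); ``items`` holds one shared parameter set
    per item — strict invariance by construction.
    """

    persons: np.ndarray
    person_ids: tuple[str, ...]
    dim_labels: tuple[str, ...]
    items: Mapping[str, ItemPair]


def draw_persons(n: int, pop: PopulationConfig, seed: int) -> np.ndarray:
    """Draw n iid person vectors from MVN(mu, D R D)."""
    w = np.linalg.eigvalsh(pop.R)
    if w.min() <= 0:
        raise ValueError(
            f"correlation matrix is not positive definite (smallest eigenvalue {w.min():.3e})"
        )
    cov = pop.R * np.outer(pop.sigma, pop.sigma)
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, pop.n_dims))
    return pop.mu + z @ L.T


def draw_items(
    item_ids: Sequence[str] | int, prior: ItemPrior, seed: int
) -> dict[str, ItemPair]:
    """Draw one shared parameter set per item from the prior."""
    if isinstance(item_ids, int):
        item_ids = [f"I{j + 1:02d}" for j in range(item_ids)]
    rng = np.random.default_rng(seed)
    out: dict[str, ItemPair] = {}
    for item in item_ids:
        a_v, a_l, a_w = np.exp(
            rng.normal(prior.alpha_logmu, prior.alpha_logsd, size=3)
        )
        d_v, d_l = rng.normal(prior.delta_mu, prior.delta_sd, size=2)
        d_w = rng.normal(prior.delta_mu + prior.delta_wid_mu, prior.delta_sd)
        t_v, t_d = np.exp(rng.normal(prior.tau_logmu, prior.tau_logsd, size=2))
        out[item] = ItemPair(
            brm=BrmItemParams(alpha=a_v, delta=d_v, tau=t_v),
            ddrm=DdrmItemParams(
                alpha_loc=a_l, delta_loc=d_l, alpha_wid=a_w, delta_wid=d_w, tau=t_d
            ),
        )
    return out


def draw_true_params(design: DesignSpec, pop: PopulationConfig, seed: int) -> TrueParams:
    """Draw person and item parameters consistent with a design."""
    labels = latent_labels(design.traits, range(1, design.n_occasions + 1))
    if pop.n_dims != len(labels):
        raise ValueError(
            f"population has {pop.n_dims} dims but design implies {len(labels)}"
        )
    persons = draw_persons(design.n_persons, pop, seed)
    items = draw_items(design.all_item_ids, pop.item_prior, seed + 1)
    return TrueParams(
        persons=persons,
        person_ids=tuple(design.person_ids),
        dim_labels=tuple(labels),
        items=items,
    )


def simulate_study(
    design: DesignSpec,
    truth: TrueParams,
    pop: PopulationConfig,
    seed: int,
    response_times: bool = True,
) -> ResponseTable:
    """Simulate one record per (person, item, occasion) slot.

    VAS slots draw a beta response proportion, DRS slots a Dirichlet
    3-simplex; both use the trait-and-occasion-appropriate person
    parameters and the item's shared parameter set, then convert back to
    raw values on the 0-100 scale.
    """
    if tuple(design.person_ids) != tuple(truth.person_ids):
        raise ValueError("design and truth person ids disagree")
    labels = truth.dim_labels
    dim_index = {lab: k for k, lab in enumerate(labels)}
    rng = np.random.default_rng(seed)
    scale = 100.0

    rows: list[dict] = []
    for occ in range(1, design.n_occasions + 1):
        for trait in design.traits:
            items = design.item_ids(trait)
            th_v = truth.persons[:, dim_index[f"theta_V_{trait}_{occ}"]]
            th_d = truth.persons[:, dim_index[f"theta_D_{trait}_{occ}"]]
            et_d = truth.persons[:, dim_index[f"eta_D_{trait}_{occ}"]]
            for item in items:
                pair = truth.items[item]
                fmts = np.array(
                    [design.format_assignment[(pid, item)] for pid in design.person_ids]
                )
                is_vas = fmts == VAS
                # BRM draw for the VAS half
                mu = expit(pair.brm.alpha * (th_v[is_vas] - pair.brm.delta))
                x = rng.beta(mu * pair.brm.tau, (1.0 - mu) * pair.brm.tau)
                vas_vals = x * scale
                # DDRM draw for the DRS half (gamma representation)
                mu_l = expit(pair.ddrm.alpha_loc * (th_d[~is_vas] - pair.ddrm.delta_loc))
                om = expit(pair.ddrm.alpha_wid * (et_d[~is_vas] - pair.ddrm.delta_wid))
                shapes = (
                    np.stack([mu_l * (1 - om), om, (1 - mu_l) * (1 - om)], axis=1)
                    * pair.ddrm.tau
                )
                g = rng.gamma(shapes)
                total = g.sum(axis=1, keepdims=True)
                bad = (total == 0).ravel()  # all-zero gamma draws at extreme shapes
                if bad.any():
                    g[bad] = shapes[bad]
                    total = g.sum(axis=1, keepdims=True)
                comp = g / total
                lows = np.clip(comp[:, 0] * scale, 0.0, scale)
                highs = np.clip((comp[:, 0] + comp[:, 1]) * scale, lows, scale)

                vi = di = 0
                for p, pid in enumerate(design.person_ids):
                    if is_vas[p]:
                        lo = hi = vas_vals[vi]
                        vi += 1
                        fmt = VAS
                    else:
                        lo, hi = lows[di], highs[di]
                        di += 1
                        fmt = DRS
                    if pop.rounding:
                        lo, hi = round(lo), round(hi)
                    rows.append(
                        {
                            "person_id": pid,
                            "item_id": item,
                            "trait": trait,
                            "occasion": occ,
                            "format": fmt,
                            "value_low": lo,
                            "value_high": hi,
                            "reverse_coded": item in design.reverse_coded_items,
                            "block_order": design.block_order[(pid, occ)],
                            "response_time_s": np.nan,
                            "serious": True,
                        }
                    )
    df = pd.DataFrame(rows)
    if response_times:
        df["response_time_s"] = rng.lognormal(
            mean=math.log(6.0), sigma=0.3, size=len(df)
        )
    # flagged items get reflected values so that un-reversing recovers the model
    rc = df["reverse_coded"].to_numpy(dtype=bool)
    if rc.any():
        lo = df.loc[rc, "value_low"].to_numpy()
        hi = df.loc[rc, "value_high"].to_numpy()
        df.loc[rc, "value_low"] = scale - hi
        df.loc[rc, "value_high"] = scale - lo
    return ResponseTable(df, scale_max=scale)


# ---------------------------------------------------------------------------
# Ready-made population mirroring the published posterior medians


# (param, trait/time cell) -> published posterior-median correlation
_PUBLISHED_CELLS: dict[tuple[str, str], float] = {
    # test-retest (T1 <-> T2, same parameter, same trait)
    ("theta_V_E_1", "theta_V_E_2"): 0.89,
    ("theta_V_C_1", "theta_V_C_2"): 0.90,
    ("theta_D_E_1", "theta_D_E_2"): 0.92,
    ("theta_D_C_1", "theta_D_C_2"): 0.87,
    ("eta_D_E_1", "eta_D_E_2"): 0.81,
    ("eta_D_C_1", "eta_D_C_2"): 0.73,
    # convergent validity (VAS location <-> DRS location, within trait/occasion)
    ("theta_V_E_1", "theta_D_E_1"): 0.93,
    ("theta_V_E_2", "theta_D_E_2"): 0.96,
    ("theta_V_C_1", "theta_D_C_1"): 0.88,
    ("theta_V_C_2", "theta_D_C_2"): 0.90,
    # DRS location <-> DRS width, within trait/occasion
    ("theta_D_E_1", "eta_D_E_1"): 0.00,
    ("theta_D_E_2", "eta_D_E_2"): -0.01,
    ("theta_D_C_1", "eta_D_C_1"): -0.11,
    ("theta_D_C_2", "eta_D_C_2"): -0.05,
    # cross-trait, same parameter and occasion
    ("theta_V_E_1", "theta_V_C_1"): 0.38,
    ("theta_V_E_2", "theta_V_C_2"): 0.34,
    ("theta_D_E_1", "theta_D_C_1"): 0.30,
    ("theta_D_E_2", "theta_D_C_2"): 0.31,
    ("eta_D_E_1", "eta_D_C_1"): 0.94,
    ("eta_D_E_2", "eta_D_C_2"): 0.96,
}


def published_correlation_cells() -> dict[tuple[str, str], float]:
    """The published posterior-median correlations, keyed by latent labels."""
    return dict(_PUBLISHED_CELLS)


def nearest_positive_definite(
    R: np.ndarray, tol: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Project a symmetric matrix to a nearby positive-definite correlation matrix.

    Alternates eigenvalue clipping at ``tol`` with rescaling to a unit
    diagonal until the smallest eigenvalue is at least ``tol``.
    """
    X = np.asarray(R, dtype=float).copy()
    for _ in range(max_iter):
        w, V = np.linalg.eigh(X)
        if w.min() >= tol:
            break
        w = np.clip(w, tol, None)
        X = (V * w) @ V.T
        s = np.sqrt(np.diag(X))
        X = X / np.outer(s, s)
        X = (X + X.T) / 2.0
        np.fill_diagonal(X, 1.0)
    return X


def _complete_by_paths(R: np.ndarray, known: np.ndarray) -> np.ndarray:
    """Fill unknown cells with signed max-|product| path correlations.

    Treating specified nonzero correlations as graph edges with weight
    ``-log |r|``, an unspecified pair is imputed as the product of the
    correlations along the strongest path.  This keeps the completed
    matrix close to internally consistent, so the subsequent
    positive-definite projection barely moves the specified cells
    (a zero fill would force compromises of up to ~0.35 on them).
    """
    d = R.shape[0]
    W = np.full((d, d), np.inf)
    for i in range(d):
        for j in range(d):
            if i != j and known[i, j] and R[i, j] != 0.0:
                W[i, j] = -math.log(abs(R[i, j]))
    dist, pred = shortest_path(W, method="D", return_predecessors=True)
    out = R.copy()
    for i in range(d):
        for j in range(i + 1, d):
            if known[i, j]:
                continue
            if not np.isfinite(dist[i, j]):
                out[i, j] = out[j, i] = 0.0
                continue
            # walk the path backwards to accumulate the sign
            sign, k = 1.0, j
            while k != i:
                p = pred[i, k]
                sign *= math.copysign(1.0, R[p, k]) if known[p, k] else 1.0
                k = p
            out[i, j] = out[j, i] = sign * math.exp(-dist[i, j])
    return out


def paper_like_population(
    traits: tuple[str, ...] = ("E", "C"),
    occasions: tuple[int, ...] = (1, 2),
    item_prior: ItemPrior | None = None,
) -> PopulationConfig:
    """A population whose correlation matrix carries the published medians.

    Specified cells hold the published posterior-median correlations;
    unspecified cells are imputed by signed path products and the result
    is projected to the nearest positive-definite correlation matrix.
    Occasion-2 means default to 0 and SDs to 1.  The default item prior
    uses precisions around 20 (moderate response noise, comparable to
    real slider data) so that simulated studies carry the measurement
    information the recovery analyses assume.
    """
    if item_prior is None:
        item_prior = ItemPrior(tau_logmu=math.log(20.0), tau_logsd=0.6)
    labels = latent_labels(traits, occasions)
    d = len(labels)
    index = {lab: k for k, lab in enumerate(labels)}
    R = np.eye(d)
    known = np.eye(d, dtype=bool)
    for (a, b), r in _PUBLISHED_CELLS.items():
        if a in index and b in index:
            i, j = index[a], index[b]
            R[i, j] = R[j, i] = r
            known[i, j] = known[j, i] = True
    R = _complete_by_paths(R, known)
    R = nearest_positive_definite(R)
    return PopulationConfig(
        mu=np.zeros(d),
        sigma=np.ones(d),
        R=R,
        item_prior=item_prior,
        dim_labels=tuple(labels),
    )
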