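"""Posterior summaries, descriptives, and derived analyses.

Highest-density intervals, correlation summaries for the three research
questions (test-retest reliability, convergent validity, discriminant
validity), the closed-form cross-lagged panel model computed per
posterior draw of the latent correlation matrix, descriptive response
statistics, cumulative interval densities, and the block-order subgroup
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DRS, VAS, ResponseTable
from .inference import ModelConfig, PosteriorDraws, fit_model
from .layout import latent_label

__all__ = [
    "hdi",
    "CorrelationSummary",
    "summarize_correlations",
    "research_question_pairs",
    "ClpmResult",
    "clpm_from_correlation",
    "clpm_from_draws",
    "descriptive_table",
    "IntervalDensity",
    "cumulative_interval_density",
    "order_effect_analysis",
]


def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    if n == 0:
        raise ValueError("hdi of empty sample")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


@dataclass(frozen=True)
class CorrelationSummary:
    """Posterior summary of one correlation-matrix entry."""

    pair: tuple[str, str]
    median: float
    hdi_low: float
    hdi_high: float
    prob_below_threshold: float
    threshold: float = 0.70

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "median": self.median,
            "hdi_low": self.hdi_low,
            "hdi_high": self.hdi_high,
            "prob_below_threshold": self.prob_below_threshold,
            "threshold": self.threshold,
        }


def summarize_correlations(
    draws: PosteriorDraws,
    pairs: list[tuple[str, str]],
    threshold: float = 0.70,
    mass: float = 0.95,
) -> list[CorrelationSummary]:
    """Median, HDI and Pr(rho < threshold) for selected correlation entries."""
    out = []
    for a, b in pairs:
        for lab in (a, b):
            if lab not in draws.dim_labels:
                raise KeyError(f"unknown latent dimension {lab!r}")
        x = draws.corr_draws(a, b)
        lo, hi = hdi(x, mass)
        out.append(
            CorrelationSummary(
                pair=(a, b),
                median=float(np.median(x)),
                hdi_low=lo,
                hdi_high=hi,
                prob_below_threshold=float(np.mean(x < threshold)),
                threshold=threshold,
            )
        )
    return out


def research_question_pairs(
    traits=("E", "C"), occasions=(1, 2)
) -> dict[str, list[tuple[str, str]]]:
    """The correlation pairs behind the three research questions.

    rq1: same parameter across occasions (test-retest reliability);
    rq2: theta_V vs theta_D and theta_D vs eta_D within trait/occasion
    (convergent validity); rq3: same parameter across traits within
    occasion (discriminant validity).
    """
    o1, o2 = occasions
    rq1 = [
        (latent_label(p, t, o1), latent_label(p, t, o2))
        for t in traits
        for p in ("theta_V", "theta_D", "eta_D")
    ]
    rq2 = []
    for t in traits:
        for o in occasions:
            rq2.append((latent_label("theta_V", t, o), latent_label("theta_D", t, o)))
            rq2.append((latent_label("theta_D", t, o), latent_label("eta_D", t, o)))
    ta, tb = traits
    rq3 = [
        (latent_label(p, ta, o), latent_label(p, tb, o))
        for p in ("theta_V", "theta_D", "eta_D")
        for o in occasions
    ]
    return {"rq1": rq1, "rq2": rq2, "rq3": rq3}


# ---------------------------------------------------------------------------
# Cross-lagged panel model


@dataclass
class ClpmResult:
    """Closed-form standardized cross-lagged regression per posterior draw.

    Variables are ordered (x1, x2, y1, y2) = (trait-A T1, trait-B T1,
    trait-A T2, trait-B T2).  ``beta11``/``beta21`` regress y1 on x1/x2;
    ``beta22``/``beta12`` regress y2 on x2/x1.  Each summary is
    (median, hdi_low, hdi_high).
    """

    beta11: tuple
    beta21: tuple
    beta22: tuple
    beta12: tuple
    rho_residual: tuple
    r2: dict[str, tuple]
    delta_r2: dict[str, tuple]
    n_draws: int
    n_skipped: int
    draws: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        def t(v):
            return {"median": v[0], "hdi_low": v[1], "hdi_high": v[2]}

        return {
            "beta11": t(self.beta11),
            "beta21": t(self.beta21),
            "beta22": t(self.beta22),
            "beta12": t(self.beta12),
            "rho_residual": t(self.rho_residual),
            "r2": {k: t(v) for k, v in self.r2.items()},
            "delta_r2": {k: t(v) for k, v in self.delta_r2.items()},
            "n_draws": self.n_draws,
            "n_skipped": self.n_skipped,
        }


def _summ(x: np.ndarray, mass: float = 0.95) -> tuple:
    lo, hi = hdi(x, mass)
    return (float(np.median(x)), lo, hi)


def clpm_from_correlation(
    R4_draws: np.ndarray,
    outcome_labels: tuple[str, str] = ("A", "B"),
    mass: float = 0.95,
) -> ClpmResult:
    """Cross-lagged panel estimates from draws of a 4x4 correlation matrix.

    For each draw the T2 outcomes are regressed on both T1 predictors in
    standardized closed form: ``beta = Rxx^-1 r_xy`` and ``R2 = r_xy'
    Rxx^-1 r_xy``.  ``delta_r2`` is the gain of the full model over the
    simple regression on the *other* trait's T1 score alone, isolating
    the unique same-trait contribution.  The T2 residual correlation is
    read off ``Ryy - Rxy' Rxx^-1 Rxy``.  Draws with singular predictor
    blocks are skipped and counted.
    """
    R = np.asarray(R4_draws, dtype=float)
    if R.ndim == 2:
        R = R[None]
    R = R.reshape(-1, 4, 4)
    if not np.allclose(R, np.swapaxes(R, 1, 2), atol=1e-8):
        raise ValueError("correlation draws must be symmetric")
    if not np.allclose(R[:, range(4), range(4)], 1.0, atol=1e-8):
        raise ValueError("correlation draws must have unit diagonal")
    acc = {k: [] for k in ("b11", "b21", "b22", "b12", "rho", "r2_a", "r2_b", "d2_a", "d2_b")}
    skipped = 0
    for Rk in R:
        Rxx = Rk[:2, :2]
        Rxy = Rk[:2, 2:]
        Ryy = Rk[2:, 2:]
        det = Rxx[0, 0] * Rxx[1, 1] - Rxx[0, 1] * Rxx[1, 0]
        if abs(det) < 1e-12:
            skipped += 1
            continue
        B = np.linalg.solve(Rxx, Rxy)  # columns: (y1, y2)
        acc["b11"].append(B[0, 0])
        acc["b21"].append(B[1, 0])
        acc["b22"].append(B[1, 1])
        acc["b12"].append(B[0, 1])
        r2_full = np.sum(Rxy * B, axis=0)  # r_xy' Rxx^-1 r_xy per outcome
        # baseline: only the other trait's T1 predictor
        r2_a_simple = Rk[1, 2] ** 2  # x2 -> y1
        r2_b_simple = Rk[0, 3] ** 2  # x1 -> y2
        acc["r2_a"].append(r2_a_simple)
        acc["r2_b"].append(r2_b_simple)
        acc["d2_a"].append(r2_full[0] - r2_a_simple)
        acc["d2_b"].append(r2_full[1] - r2_b_simple)
        resid = Ryy - Rxy.T @ B
        denom = np.sqrt(resid[0, 0] * resid[1, 1])
        acc["rho"].append(resid[0, 1] / denom if denom > 0 else np.nan)
    if not acc["b11"]:
        raise ValueError("all draws were singular")
    arr = {k: np.asarray(v) for k, v in acc.items()}
    rho = arr["rho"][~np.isnan(arr["rho"])]
    la, lb = outcome_labels
    return ClpmResult(
        beta11=_summ(arr["b11"], mass),
        beta21=_summ(arr["b21"], mass),
        beta22=_summ(arr["b22"], mass),
        beta12=_summ(arr["b12"], mass),
        rho_residual=_summ(rho if len(rho) else arr["rho"], mass),
        r2={la: _summ(arr["r2_a"], mass), lb: _summ(arr["r2_b"], mass)},
        delta_r2={la: _summ(arr["d2_a"], mass), lb: _summ(arr["d2_b"], mass)},
        n_draws=len(arr["b11"]),
        n_skipped=skipped,
        draws=arr,
    )


def clpm_from_draws(
    draws: PosteriorDraws,
    param: str = "eta_D",
    traits: tuple[str, str] = ("E", "C"),
    occasions: tuple[int, int] = (1, 2),
) -> ClpmResult:
    """CLPM on the 4x4 sub-block of the posterior correlation draws.

    Default: DRS widths of both traits, T2 regressed on T1.
    """
    labels = [latent_label(param, t, o) for o in occasions for t in traits]
    idx = [draws.dim_index(lab) for lab in labels]
    R4 = draws.corr[..., idx, :][..., idx]
    R4 = R4.reshape(-1, 4, 4)
    return clpm_from_correlation(R4, outcome_labels=traits)


# ---------------------------------------------------------------------------
# Descriptives


def descriptive_table(table: ResponseTable) -> pd.DataFrame:
    """Mean/SD of person-averaged response summaries per trait and occasion.

    Averages within person first, then across persons.  Columns cover
    the VAS value, the DRS location (midpoint of the bounds), DRS width,
    and the DRS lower/upper bounds.  Reverse coding must already be
    applied.
    """
    if table.df["reverse_coded"].any():
        raise ValueError("apply reverse coding before computing descriptives")
    df = table.df
    rows = []
    for (trait, occ), g in df.groupby(["trait", "occasion"]):
        row: dict = {"trait": trait, "occasion": int(occ)}
        vas = g[g["format"] == VAS]
        per = vas.groupby("person_id")["value_low"].mean()
        row["vas_mean"], row["vas_sd"] = per.mean(), per.std(ddof=1)
        drs = g[g["format"] == DRS].copy()
        drs["location"] = (drs["value_low"] + drs["value_high"]) / 2.0
        drs["width"] = drs["value_high"] - drs["value_low"]
        for name, col in (
            ("drs_location", "location"),
            ("drs_width", "width"),
            ("drs_lb", "value_low"),
            ("drs_ub", "value_high"),
        ):
            per = drs.groupby("person_id")[col].mean()
            row[f"{name}_mean"], row[f"{name}_sd"] = per.mean(), per.std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["trait", "occasion"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cumulative interval densities


@dataclass
class IntervalDensity:
    """Containment-count density of one person's response intervals.

    ``density[i]`` counts how many intervals contain ``grid[i]``.  The
    median and outer quantiles refer to the cumulated value mass (each
    interval contributing uniform mass proportional to its width).
    """

    grid: np.ndarray
    density: np.ndarray
    median: float
    q_low: float
    q_high: float
    total_mass: float


def cumulative_interval_density(
    intervals,
    grid_step: float = 0.1,
    scale_max: float = 100.0,
    q: tuple[float, float] = (0.025, 0.975),
) -> IntervalDensity:
    """Accumulate the values contained in a set of response intervals.

    ``intervals`` is an iterable of (low, high) pairs (one person's DRS
    responses for one trait and occasion).  The density at x is the
    number of intervals with ``low <= x <= high``; quantiles of the
    cumulated mass are computed exactly from the piecewise-linear CDF.
    """
    pairs = np.asarray(list(intervals), dtype=float).reshape(-1, 2)
    if len(pairs) == 0:
        raise ValueError("no intervals given")
    lows, highs = pairs[:, 0], pairs[:, 1]
    if np.any(lows > highs):
        raise ValueError("interval with low > high")
    grid = np.arange(0.0, scale_max + grid_step / 2, grid_step)
    density = (
        (grid[None, :] >= lows[:, None]) & (grid[None, :] <= highs[:, None])
    ).sum(axis=0)

    widths = highs - lows
    total = float(widths.sum())
    if total == 0.0:
        # all point intervals: quantiles over the point masses
        mids = (lows + highs) / 2.0
        med = float(np.quantile(mids, 0.5))
        ql, qh = (float(np.quantile(mids, p)) for p in q)
        return IntervalDensity(grid, density, med, ql, qh, 0.0)

    # piecewise-linear CDF of the cumulated mass
    points = np.unique(np.concatenate([lows, highs]))
    counts = (
        (points[:-1][None, :] >= lows[:, None] - 1e-12)
        & (points[1:][None, :] <= highs[:, None] + 1e-12)
    ).sum(axis=0)
    seg = np.diff(points) * counts
    cum = np.concatenate([[0.0], np.cumsum(seg)])

    def invert(p: float) -> float:
        target = p * total
        k = int(np.searchsorted(cum, target, side="right")) - 1
        k = min(max(k, 0), len(seg) - 1)
        if seg[k] == 0:
            return float(points[k])
        frac = (target - cum[k]) / seg[k]
        return float(points[k] + frac * (points[k + 1] - points[k]))

    return IntervalDensity(
        grid=grid,
        density=density,
        median=invert(0.5),
        q_low=invert(q[0]),
        q_high=invert(q[1]),
        total_mass=total,
    )


# ---------------------------------------------------------------------------
# Block-order subgroup analysis


def order_effect_analysis(
    table: ResponseTable,
    cfg: ModelConfig | None = None,
    occasion: int | None = None,
    **fit_kw,
) -> dict[str, list[CorrelationSummary]]:
    """Fit the model separately per block order and compare theta_V-theta_D.

    Uses first-occasion data only (carry-over effects concern the order
    within one session).  Returns per-order correlation summaries of the
    VAS-DRS location convergence for every trait.
    """
    occ = occasion if occasion is not None else table.occasions[0]
    df = table.df[table.df["occasion"] == occ]
    orders = sorted(df["block_order"].unique())
    if len(orders) < 2:
        raise ValueError("both block orders must be present")
    out: dict[str, list[CorrelationSummary]] = {}
    sizes = {}
    for order in orders:
        sub = ResponseTable(
            df[df["block_order"] == order].reset_index(drop=True), table.scale_max
        )
        if len(sub) == 0:
            raise ValueError(f"empty subgroup for block order {order!r}")
        sizes[order] = len(sub.persons)
        draws = fit_model(sub, cfg, **fit_kw)
        pairs = [
            (latent_label("theta_V", t, occ), latent_label("theta_D", t, occ))
            for t in sub.traits
        ]
        out[order] = summarize_correlations(draws, pairs)
    return out
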