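"""Longitudinal measurement-invariance ladder.

Separate sub-models per trait x response format, fitted at four levels
of cross-occasion equality constraints on the item parameters —
configural (none), metric (scaling), scalar (scaling + difficulty),
strict (all, including precision) — and compared by differences in
PSIS-LOO expected log predictive density, with the standard error of
each difference computed from the pointwise elpd difference vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ResponseTable
from .inference import (
    INVARIANCE_LEVELS,
    LooResult,
    ModelConfig,
    PosteriorDraws,
    compute_loo,
    fit_model,
)

__all__ = [
    "InvarianceLadderResult",
    "fit_submodel",
    "invariance_ladder",
    "elpd_difference",
]


@dataclass
class LadderRow:
    level: str
    elpd_loo: float
    se: float
    delta_elpd: float | None = None  # vs the previous (less constrained) level
    delta_se: float | None = None
    converged: bool = True


@dataclass
class InvarianceLadderResult:
    """Four stacked fits and their adjacent-pair LOO comparisons.

    The configural row carries the absolute elpd_loo; subsequent rows
    additionally carry the difference to the previous row.  ``winner``
    is the level with the highest elpd_loo; ``practically_equivalent``
    marks winners within 2 SE of the runner-up difference.
    """

    trait: str
    format: str
    rows: list[LadderRow] = field(default_factory=list)
    flagged: bool = False  # any non-converged fit

    @property
    def winner(self) -> str:
        best = max(self.rows, key=lambda r: r.elpd_loo)
        return best.level

    @property
    def practically_equivalent(self) -> bool:
        ranked = sorted(self.rows, key=lambda r: r.elpd_loo, reverse=True)
        if len(ranked) < 2:
            return False
        return abs(ranked[0].elpd_loo - ranked[1].elpd_loo) < 2.0 * (
            ranked[1].delta_se or ranked[0].se
        )

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "format": self.format,
            "winner": self.winner,
            "flagged": self.flagged,
            "rows": [
                {
                    "level": r.level,
                    "elpd_loo": r.elpd_loo,
                    "se": r.se,
                    "delta_elpd": r.delta_elpd,
                    "delta_se": r.delta_se,
                    "converged": r.converged,
                }
                for r in self.rows
            ],
        }


def fit_submodel(
    table: ResponseTable,
    trait: str,
    format: str,
    level: str,
    cfg: ModelConfig | None = None,
    **kw,
) -> PosteriorDraws:
    """Fit one trait/format sub-model at a given invariance level.

    The sub-model keeps the person structure of the joint model
    restricted to its own latent dimensions (first-occasion means/SDs
    fixed, later occasions free, full correlation across occasions).
    """
    if level not in INVARIANCE_LEVELS:
        raise ValueError(f"unknown invariance level {level!r}")
    sub = table.subset(
        (table.df["trait"] == trait) & (table.df["format"] == format)
    )
    if len(sub) == 0:
        raise ValueError(f"no records for trait {trait!r} format {format!r}")
    if len(sub.occasions) < 2:
        raise ValueError("invariance sub-models require at least two occasions")
    return fit_model(sub, cfg, invariance_level=level, **kw)


def elpd_difference(a: LooResult, b: LooResult) -> tuple[float, float]:
    """elpd_loo(a) - elpd_loo(b) with SE from the pointwise differences."""
    if a.n != b.n:
        raise ValueError("LOO results cover different observation sets")
    d = a.elpd_i - b.elpd_i
    return float(d.sum()), float(np.sqrt(len(d) * np.var(d, ddof=1))) if len(d) > 1 else 0.0


def invariance_ladder(
    table: ResponseTable,
    trait: str,
    format: str,
    cfg: ModelConfig | None = None,
) -> InvarianceLadderResult:
    """Fit configural -> metric -> scalar -> strict and compare by LOO."""
    result = InvarianceLadderResult(trait=trait, format=format)
    prev_loo: LooResult | None = None
    for level in INVARIANCE_LEVELS:
        draws = fit_submodel(
            table, trait, format, level, cfg,
            store_loglik=True, diagnose_person=False,
        )
        loo = compute_loo(draws)
        row = LadderRow(
            level=level,
            elpd_loo=loo.elpd_loo,
            se=loo.se,
            converged=draws.diagnostics.passed if draws.diagnostics else True,
        )
        if prev_loo is not None:
            row.delta_elpd, row.delta_se = elpd_difference(loo, prev_loo)
        if not row.converged:
            result.flagged = True
        result.rows.append(row)
        prev_loo = loo
    return result
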