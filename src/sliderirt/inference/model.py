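"""Joint hierarchical model: log posterior density and analytic gradient.

The model couples beta (VAS) and Dirichlet (DRS) measurement densities
over all traits, formats and occasions with a multivariate-normal
population distribution for the latent person vector.  Identification:
first-occasion factor means are fixed at 0 and SDs at 1; remaining means
and SDs are free.  The correlation matrix is parameterised by its
Cholesky factor via tanh-transformed canonical partial correlations with
an LKJ prior; the person vectors are non-centered.

Everything is hand-vectorised NumPy so the sampler needs no autodiff
framework.  The unconstrained parameter vector is laid out as::

    [ u (P*d) | mu_free | log_sigma_free | y_chol |
      brm: log_alpha, delta, log_tau |
      ddrm: log_alpha_loc, log_alpha_wid, delta_loc, delta_wid, log_tau ]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, expit, gammaln, psi

from ..design import DRS, VAS, ResponseTable
from ..layout import latent_label
from . import kernels

__all__ = ["PriorConfig", "SliderModel", "INVARIANCE_LEVELS"]

INVARIANCE_LEVELS = ("configural", "metric", "scalar", "strict")

_SHARED_CLASSES = {
    "configural": frozenset(),
    "metric": frozenset({"alpha"}),
    "scalar": frozenset({"alpha", "delta"}),
    "strict": frozenset({"alpha", "delta", "tau"}),
}


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors for all non-person parameters."""

    alpha_logmu: float = 0.0
    alpha_logsd: float = 0.5
    delta_mu: float = 0.0
    delta_sd: float = 1.0
    tau_logmu: float = math.log(10.0)
    tau_logsd: float = 1.0
    lkj_eta: float = 1.0
    mean_sd: float = 1.0  # free factor means ~ Normal(0, mean_sd)
    sd_scale: float = 1.0  # free factor SDs ~ half-Normal(sd_scale)


def _chol_from_z(z: np.ndarray) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial correlations."""
    d = z.shape[0]
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    for i in range(1, d):
        s = 1.0
        for j in range(i):
            L[i, j] = z[i, j] * math.sqrt(s)
            s *= 1.0 - z[i, j] ** 2
        L[i, i] = math.sqrt(s)
    return L


def _chol_pullback(z: np.ndarray, gL: np.ndarray) -> np.ndarray:
    """Reverse-mode gradient of `_chol_from_z`: dlogp/dL -> dlogp/dz."""
    d = z.shape[0]
    gz = np.zeros_like(z)
    for i in range(1, d):
        s = np.empty(i + 1)
        s[0] = 1.0
        for j in range(i):
            s[j + 1] = s[j] * (1.0 - z[i, j] ** 2)
        gs = gL[i, i] * 0.5 / math.sqrt(s[i])
        for j in range(i - 1, -1, -1):
            zij = z[i, j]
            rt = math.sqrt(s[j])
            gz[i, j] = gL[i, j] * rt - gs * 2.0 * zij * s[j]
            gs = gs * (1.0 - zij**2) + gL[i, j] * zij * 0.5 / rt
    return gz


def _group_index(items, occs, shared: bool):
    """Map each record to a parameter-group column; one group per item,
    or per (item, occasion) when the parameter class is occasion-specific."""
    keys = [it if shared else (it, oc) for it, oc in zip(items, occs)]
    uniq = sorted(set(keys), key=repr)
    index = {k: i for i, k in enumerate(uniq)}
    return np.array([index[k] for k in keys], dtype=np.intp), uniq


class SliderModel:
    """Log posterior of the joint (or restricted) hierarchical model.

    Parameters
    ----------
    table : ResponseTable
        Preprocessed responses.  May be restricted to a single trait
        and/or format (sub-models for the invariance ladder) or a single
        occasion (all latent dimensions then fixed to the identified
        scale).
    invariance_level : str
        One of ``configural``, ``metric``, ``scalar``, ``strict``;
        controls which item-parameter classes share one set across
        occasions.
    priors : PriorConfig
    """

    def __init__(
        self,
        table: ResponseTable,
        invariance_level: str = "strict",
        priors: PriorConfig = PriorConfig(),
        use_numba: bool = True,
    ):
        if invariance_level not in INVARIANCE_LEVELS:
            raise ValueError(f"unknown invariance level {invariance_level!r}")
        df = table.df
        if df.duplicated(subset=["person_id", "item_id", "occasion"]).any():
            raise ValueError("table contains duplicate records; preprocess first")
        self.level = invariance_level
        self.priors = priors
        self.scale_max = table.scale_max
        self.n_records = len(df)

        self.occasions = sorted(int(o) for o in df["occasion"].unique())
        self.persons = sorted(df["person_id"].unique())
        if len(self.persons) < 2:
            raise ValueError(
                "at least two persons are required (correlations unidentifiable)"
            )
        occ_sets = df.groupby("person_id")["occasion"].agg(set)
        want = set(self.occasions)
        for pid, got in occ_sets.items():
            if got != want:
                raise ValueError(
                    f"person {pid!r} lacks records at occasion(s) {sorted(want - got)}"
                )

        self.traits = sorted(df["trait"].unique())
        has_vas = {t: bool(((df["trait"] == t) & (df["format"] == VAS)).any()) for t in self.traits}
        has_drs = {t: bool(((df["trait"] == t) & (df["format"] == DRS)).any()) for t in self.traits}
        dims: list[str] = []
        for occ in self.occasions:
            for t in self.traits:
                if has_vas[t]:
                    dims.append(latent_label("theta_V", t, occ))
                if has_drs[t]:
                    dims.append(latent_label("theta_D", t, occ))
                    dims.append(latent_label("eta_D", t, occ))
        self.dim_labels = dims
        self.d = len(dims)
        dim_index = {lab: k for k, lab in enumerate(dims)}
        first = self.occasions[0]
        self.fixed_dim = np.array(
            [lab.rsplit("_", 1)[1] == str(first) for lab in dims]
        )
        self.free_idx = np.where(~self.fixed_dim)[0]
        self.nf = len(self.free_idx)
        self.P = len(self.persons)
        person_index = {p: i for i, p in enumerate(self.persons)}

        shared = _SHARED_CLASSES[invariance_level]
        n = self.n_records  # compression denominator

        vas = df[df["format"] == VAS]
        self.v_rows = vas.index.to_numpy()
        self.v_person = vas["person_id"].map(person_index).to_numpy(dtype=np.intp)
        self.v_dim = np.array(
            [
                dim_index[latent_label("theta_V", t, int(o))]
                for t, o in zip(vas["trait"], vas["occasion"])
            ],
            dtype=np.intp,
        )
        v_items, v_occs = vas["item_id"].to_numpy(), vas["occasion"].to_numpy()
        self.v_ia, self.brm_alpha_keys = _group_index(v_items, v_occs, "alpha" in shared)
        self.v_id, self.brm_delta_keys = _group_index(v_items, v_occs, "delta" in shared)
        self.v_it, self.brm_tau_keys = _group_index(v_items, v_occs, "tau" in shared)
        x = vas["value_low"].to_numpy() / self.scale_max
        x = (x * (n - 1) + 0.5) / n
        self.v_logx = np.log(x)
        self.v_log1mx = np.log1p(-x)

        drs = df[df["format"] == DRS]
        self.d_rows = drs.index.to_numpy()
        self.d_person = drs["person_id"].map(person_index).to_numpy(dtype=np.intp)
        self.d_dimt = np.array(
            [
                dim_index[latent_label("theta_D", t, int(o))]
                for t, o in zip(drs["trait"], drs["occasion"])
            ],
            dtype=np.intp,
        )
        self.d_dime = np.array(
            [
                dim_index[latent_label("eta_D", t, int(o))]
                for t, o in zip(drs["trait"], drs["occasion"])
            ],
            dtype=np.intp,
        )
        d_items, d_occs = drs["item_id"].to_numpy(), drs["occasion"].to_numpy()
        self.d_ia, self.ddrm_alpha_keys = _group_index(d_items, d_occs, "alpha" in shared)
        self.d_id, self.ddrm_delta_keys = _group_index(d_items, d_occs, "delta" in shared)
        self.d_it, self.ddrm_tau_keys = _group_index(d_items, d_occs, "tau" in shared)
        lo = drs["value_low"].to_numpy() / self.scale_max
        hi = drs["value_high"].to_numpy() / self.scale_max
        comp = np.stack([lo, hi - lo, 1.0 - hi], axis=1)
        comp = (comp * (n - 1) + 1.0 / 3.0) / n
        self.d_logx = np.log(comp)

        # parameter vector layout
        sizes = {
            "u": self.P * self.d,
            "mu_free": self.nf,
            "log_sigma_free": self.nf,
            "y_chol": self.d * (self.d - 1) // 2,
            "brm_log_alpha": len(self.brm_alpha_keys),
            "brm_delta": len(self.brm_delta_keys),
            "brm_log_tau": len(self.brm_tau_keys),
            "ddrm_log_alpha_loc": len(self.ddrm_alpha_keys),
            "ddrm_log_alpha_wid": len(self.ddrm_alpha_keys),
            "ddrm_delta_loc": len(self.ddrm_delta_keys),
            "ddrm_delta_wid": len(self.ddrm_delta_keys),
            "ddrm_log_tau": len(self.ddrm_tau_keys),
        }
        self.slices: dict[str, slice] = {}
        off = 0
        for name, size in sizes.items():
            self.slices[name] = slice(off, off + size)
            off += size
        self.n_params = off
        self.v_flat = self.v_person * self.d + self.v_dim
        self.d_flat_t = self.d_person * self.d + self.d_dimt
        self.d_flat_e = self.d_person * self.d + self.d_dime
        self._use_numba = bool(use_numba and kernels.HAVE_NUMBA)
        self._tril = np.tril_indices(self.d, k=-1)
        # coefficient on log(1 - z^2): LKJ prior + Cholesky-map and tanh Jacobians
        cols1 = self._tril[1] + 1  # 1-based column
        self._lkj_coef = (self.d + 2.0 * priors.lkj_eta - 1.0 - cols1) / 2.0

    # -- helpers -----------------------------------------------------------

    def _unpack_corr(self, vec):
        y = vec[self.slices["y_chol"]]
        z = np.zeros((self.d, self.d))
        z[self._tril] = np.tanh(y)
        L = _chol_from_z(z)
        return y, z, L

    def _mu_sigma(self, vec):
        mu = np.zeros(self.d)
        sigma = np.ones(self.d)
        if self.nf:
            mu[self.free_idx] = vec[self.slices["mu_free"]]
            sigma[self.free_idx] = np.exp(vec[self.slices["log_sigma_free"]])
        return mu, sigma

    def latent(self, vec: np.ndarray) -> np.ndarray:
        """Person latent matrix (P, d) implied by an unconstrained vector."""
        _, _, L = self._unpack_corr(vec)
        mu, sigma = self._mu_sigma(vec)
        U = vec[self.slices["u"]].reshape(self.P, self.d)
        return mu + (U @ L.T) * sigma

    def metric_init(self) -> np.ndarray:
        """Prior-scale guess of posterior variances (initial inverse mass)."""
        inv = np.ones(self.n_params)
        pr = self.priors
        inv[self.slices["log_sigma_free"]] = 0.25
        inv[self.slices["y_chol"]] = 0.1
        for name in ("brm_log_alpha", "ddrm_log_alpha_loc", "ddrm_log_alpha_wid"):
            inv[self.slices[name]] = pr.alpha_logsd**2
        inv[self.slices["brm_log_tau"]] = 0.25
        inv[self.slices["ddrm_log_tau"]] = 0.25
        return inv

    def initial_value(self, rng: np.random.Generator) -> np.ndarray:
        vec = 0.2 * rng.standard_normal(self.n_params)
        for name in ("brm_log_tau", "ddrm_log_tau"):
            vec[self.slices[name]] += self.priors.tau_logmu
        return vec

    # -- density -----------------------------------------------------------

    def logp_grad(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        """Log posterior (up to a constant) and its gradient.

        Returns ``(-inf, zeros)`` outside the numerically supported
        region (saturated links, overflowing precisions); the sampler
        treats such states as divergent.
        """
        with np.errstate(all="ignore"):
            logp, grad = self._logp_grad_raw(vec)
        if not np.isfinite(logp) or not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(vec)
        return logp, grad

    def _logp_grad_raw(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        pr = self.priors
        grad = np.zeros_like(vec)
        y, z, L = self._unpack_corr(vec)
        mu, sigma = self._mu_sigma(vec)
        U = vec[self.slices["u"]].reshape(self.P, self.d)
        V = U @ L.T  # correlated standard deviates
        lat = mu + V * sigma

        logp = 0.0
        G = np.zeros((self.P, self.d))  # dlogp/dlatent

        if self._use_numba:
            logp += self._likelihood_numba(vec, grad, lat, G)
        else:
            logp += self._likelihood_numpy(vec, grad, lat, G)
        if not np.isfinite(logp):
            return -np.inf, grad

        # ---- propagate latent gradient to u, mu, sigma, correlation
        gU = (G * sigma) @ L
        grad[self.slices["u"]] += gU.ravel()
        if self.nf:
            grad[self.slices["mu_free"]] += G.sum(axis=0)[self.free_idx]
            gsig = np.sum(G * V, axis=0)
            grad[self.slices["log_sigma_free"]] += (
                gsig[self.free_idx] * sigma[self.free_idx]
            )
        gL = sigma[:, None] * (G.T @ U)
        gz = _chol_pullback(z, np.tril(gL, k=-1) + np.diag(np.diag(gL)))
        zt = z[self._tril]
        grad[self.slices["y_chol"]] += gz[self._tril] * (1.0 - zt**2)

        # ---- priors
        uflat = vec[self.slices["u"]]
        logp += -0.5 * float(uflat @ uflat)
        grad[self.slices["u"]] -= uflat

        if self.nf:
            mf = vec[self.slices["mu_free"]]
            logp += -0.5 * float(mf @ mf) / pr.mean_sd**2
            grad[self.slices["mu_free"]] -= mf / pr.mean_sd**2
            ls = vec[self.slices["log_sigma_free"]]
            s = np.exp(ls)
            logp += float(np.sum(-0.5 * s**2 / pr.sd_scale**2 + ls))
            grad[self.slices["log_sigma_free"]] += -(s**2) / pr.sd_scale**2 + 1.0

        logp += float(np.sum(self._lkj_coef * np.log1p(-zt**2)))
        grad[self.slices["y_chol"]] += -2.0 * self._lkj_coef * zt

        for name, mu0, sd0 in (
            ("brm_log_alpha", pr.alpha_logmu, pr.alpha_logsd),
            ("brm_delta", pr.delta_mu, pr.delta_sd),
            ("brm_log_tau", pr.tau_logmu, pr.tau_logsd),
            ("ddrm_log_alpha_loc", pr.alpha_logmu, pr.alpha_logsd),
            ("ddrm_log_alpha_wid", pr.alpha_logmu, pr.alpha_logsd),
            ("ddrm_delta_loc", pr.delta_mu, pr.delta_sd),
            ("ddrm_delta_wid", pr.delta_mu, pr.delta_sd),
            ("ddrm_log_tau", pr.tau_logmu, pr.tau_logsd),
        ):
            x = vec[self.slices[name]]
            if len(x):
                logp += -0.5 * float(np.sum((x - mu0) ** 2)) / sd0**2
                grad[self.slices[name]] -= (x - mu0) / sd0**2

        return logp, grad

    def _likelihood_numba(self, vec, grad, lat, G) -> float:
        """Fused-kernel likelihood; accumulates gradients in place."""
        logp = 0.0
        lat_flat = np.ascontiguousarray(lat.ravel())
        G_flat = G.reshape(-1)
        from scipy.special import gammaln as _gammaln, psi as _psi

        if len(self.v_person):
            al = np.exp(vec[self.slices["brm_log_alpha"]])
            de = np.array(vec[self.slices["brm_delta"]])
            ta = np.exp(vec[self.slices["brm_log_tau"]])
            lp = kernels.vas_block(
                lat_flat, self.d,
                self.v_person, self.v_dim, self.v_ia, self.v_id, self.v_it,
                al, de, ta, _psi(ta), _gammaln(ta),
                self.v_logx, self.v_log1mx,
                G_flat,
                grad[self.slices["brm_log_alpha"]],
                grad[self.slices["brm_delta"]],
                grad[self.slices["brm_log_tau"]],
            )
            if not np.isfinite(lp):
                return -np.inf
            logp += lp
        if len(self.d_person):
            all_ = np.exp(vec[self.slices["ddrm_log_alpha_loc"]])
            alw = np.exp(vec[self.slices["ddrm_log_alpha_wid"]])
            dll = np.array(vec[self.slices["ddrm_delta_loc"]])
            dlw = np.array(vec[self.slices["ddrm_delta_wid"]])
            tad = np.exp(vec[self.slices["ddrm_log_tau"]])
            lp = kernels.drs_block(
                lat_flat, self.d,
                self.d_person, self.d_dimt, self.d_dime,
                self.d_ia, self.d_id, self.d_it,
                all_, alw, dll, dlw, tad, _psi(tad), _gammaln(tad),
                self.d_logx[:, 0], self.d_logx[:, 1], self.d_logx[:, 2],
                G_flat,
                grad[self.slices["ddrm_log_alpha_loc"]],
                grad[self.slices["ddrm_log_alpha_wid"]],
                grad[self.slices["ddrm_delta_loc"]],
                grad[self.slices["ddrm_delta_wid"]],
                grad[self.slices["ddrm_log_tau"]],
            )
            if not np.isfinite(lp):
                return -np.inf
            logp += lp
        return logp

    def _likelihood_numpy(self, vec, grad, lat, G) -> float:
        logp = 0.0
        # ---- BRM likelihood
        if len(self.v_person):
            al = np.exp(vec[self.slices["brm_log_alpha"]])
            de = vec[self.slices["brm_delta"]]
            ta = np.exp(vec[self.slices["brm_log_tau"]])
            a_r, d_r, t_r = al[self.v_ia], de[self.v_id], ta[self.v_it]
            th = lat[self.v_person, self.v_dim]
            m = expit(a_r * (th - d_r))
            a = m * t_r
            b = (1.0 - m) * t_r
            # tau-only terms evaluated once per parameter group
            glnt = gammaln(ta)[self.v_it]
            logp += float(
                np.sum(
                    (a - 1.0) * self.v_logx
                    + (b - 1.0) * self.v_log1mx
                    - gammaln(a)
                    - gammaln(b)
                    + glnt
                )
            )
            psit = psi(ta)[self.v_it]
            ga = self.v_logx - psi(a) + psit
            gb = self.v_log1mx - psi(b) + psit
            gm = (ga - gb) * t_r
            gt = ga * m + gb * (1.0 - m)
            mm = m * (1.0 - m)
            gth = gm * mm * a_r
            G += np.bincount(
                self.v_flat, gth, minlength=self.P * self.d
            ).reshape(self.P, self.d)
            grad[self.slices["brm_log_alpha"]] += np.bincount(
                self.v_ia, gm * mm * (th - d_r) * a_r, minlength=len(al)
            )
            grad[self.slices["brm_delta"]] += np.bincount(
                self.v_id, -gm * mm * a_r, minlength=len(de)
            )
            grad[self.slices["brm_log_tau"]] += np.bincount(
                self.v_it, gt * t_r, minlength=len(ta)
            )

        # ---- DDRM likelihood
        if len(self.d_person):
            all_ = np.exp(vec[self.slices["ddrm_log_alpha_loc"]])
            alw = np.exp(vec[self.slices["ddrm_log_alpha_wid"]])
            dll = vec[self.slices["ddrm_delta_loc"]]
            dlw = vec[self.slices["ddrm_delta_wid"]]
            tad = np.exp(vec[self.slices["ddrm_log_tau"]])
            al_r, aw_r = all_[self.d_ia], alw[self.d_ia]
            dl_r, dw_r = dll[self.d_id], dlw[self.d_id]
            t_r = tad[self.d_it]
            th = lat[self.d_person, self.d_dimt]
            et = lat[self.d_person, self.d_dime]
            m = expit(al_r * (th - dl_r))
            w = expit(aw_r * (et - dw_r))
            shp = np.stack([m * (1 - w), w, (1 - m) * (1 - w)], axis=1) * t_r[:, None]
            logp += float(
                np.sum((shp - 1.0) * self.d_logx)
                - np.sum(gammaln(shp))
                + np.sum(gammaln(tad)[self.d_it])
            )
            g = self.d_logx - psi(shp) + psi(tad)[self.d_it, None]
            gm = t_r * (1.0 - w) * (g[:, 0] - g[:, 2])
            gw = t_r * (g[:, 1] - m * g[:, 0] - (1.0 - m) * g[:, 2])
            gt = np.sum(g * shp / t_r[:, None], axis=1)
            mm = m * (1.0 - m)
            ww = w * (1.0 - w)
            G += np.bincount(
                self.d_flat_t, gm * mm * al_r, minlength=self.P * self.d
            ).reshape(self.P, self.d)
            G += np.bincount(
                self.d_flat_e, gw * ww * aw_r, minlength=self.P * self.d
            ).reshape(self.P, self.d)
            grad[self.slices["ddrm_log_alpha_loc"]] += np.bincount(
                self.d_ia, gm * mm * (th - dl_r) * al_r, minlength=len(all_)
            )
            grad[self.slices["ddrm_log_alpha_wid"]] += np.bincount(
                self.d_ia, gw * ww * (et - dw_r) * aw_r, minlength=len(alw)
            )
            grad[self.slices["ddrm_delta_loc"]] += np.bincount(
                self.d_id, -gm * mm * al_r, minlength=len(dll)
            )
            grad[self.slices["ddrm_delta_wid"]] += np.bincount(
                self.d_id, -gw * ww * aw_r, minlength=len(dlw)
            )
            grad[self.slices["ddrm_log_tau"]] += np.bincount(
                self.d_it, gt * t_r, minlength=len(tad)
            )
        return logp

    def logp(self, vec: np.ndarray) -> float:
        return self.logp_grad(vec)[0]

    # -- pointwise log-likelihood (for LOO) --------------------------------

    def pointwise_loglik(self, vec: np.ndarray) -> np.ndarray:
        """Per-record log-likelihood in table row order."""
        out = np.empty(self.n_records)
        lat = self.latent(vec)
        if len(self.v_person):
            al = np.exp(vec[self.slices["brm_log_alpha"]])[self.v_ia]
            de = vec[self.slices["brm_delta"]][self.v_id]
            ta = np.exp(vec[self.slices["brm_log_tau"]])[self.v_it]
            th = lat[self.v_person, self.v_dim]
            m = expit(al * (th - de))
            a, b = m * ta, (1.0 - m) * ta
            out[self.v_rows] = (
                (a - 1.0) * self.v_logx + (b - 1.0) * self.v_log1mx - betaln(a, b)
            )
        if len(self.d_person):
            al = np.exp(vec[self.slices["ddrm_log_alpha_loc"]])[self.d_ia]
            aw = np.exp(vec[self.slices["ddrm_log_alpha_wid"]])[self.d_ia]
            dl = vec[self.slices["ddrm_delta_loc"]][self.d_id]
            dw = vec[self.slices["ddrm_delta_wid"]][self.d_id]
            ta = np.exp(vec[self.slices["ddrm_log_tau"]])[self.d_it]
            th = lat[self.d_person, self.d_dimt]
            et = lat[self.d_person, self.d_dime]
            m = expit(al * (th - dl))
            w = expit(aw * (et - dw))
            shp = np.stack([m * (1 - w), w, (1 - m) * (1 - w)], axis=1) * ta[:, None]
            out[self.d_rows] = (
                np.sum((shp - 1.0) * self.d_logx, axis=1)
                - np.sum(gammaln(shp), axis=1)
                + gammaln(ta)
            )
        return out

    # -- structured view ---------------------------------------------------

    def unpack(self, vec: np.ndarray) -> dict:
        """Natural-scale parameter values from an unconstrained vector."""
        _, _, L = self._unpack_corr(vec)
        mu, sigma = self._mu_sigma(vec)
        out = {
            "person": self.latent(vec),
            "corr": L @ L.T,
            "mu": mu,
            "sigma": sigma,
            "brm_alpha": np.exp(vec[self.slices["brm_log_alpha"]]),
            "brm_delta": np.array(vec[self.slices["brm_delta"]]),
            "brm_tau": np.exp(vec[self.slices["brm_log_tau"]]),
            "ddrm_alpha_loc": np.exp(vec[self.slices["ddrm_log_alpha_loc"]]),
            "ddrm_alpha_wid": np.exp(vec[self.slices["ddrm_log_alpha_wid"]]),
            "ddrm_delta_loc": np.array(vec[self.slices["ddrm_delta_loc"]]),
            "ddrm_delta_wid": np.array(vec[self.slices["ddrm_delta_wid"]]),
            "ddrm_tau": np.exp(vec[self.slices["ddrm_log_tau"]]),
        }
        return out
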