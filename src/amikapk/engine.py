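"""Vectorised closed-form prediction over a packed study design.

The estimation and simulation-based diagnostics need population and
individual predictions for every observation of every subject many
thousands of times.  :class:`PackedDesign` flattens a :class:`Dataset`
into padded numpy arrays (subjects x observations x doses) and
precomputes the time geometry, so that one prediction pass is a
handful of vectorised exponentials.  Batched parameter arrays with
leading dimensions (e.g. simulation replicates) broadcast through
:meth:`PackedDesign.pred`.
"""

from __future__ import annotations

import numpy as np

from .dataset import Dataset
from .model import PopulationModel

__all__ = ["PackedDesign"]

_COVS = ("wt", "pma", "ga", "pna", "scr")


class PackedDesign:
    """Padded array view of a dataset's doses, observations and covariates."""

    def __init__(self, dataset: Dataset):
        S = len(dataset)
        Tmax = max((s.n_obs for s in dataset), default=0) or 1
        Dmax = max((len(s.doses) for s in dataset), default=0) or 1

        self.ids = [s.id for s in dataset]
        self.n_subjects = S
        self.t = np.zeros((S, Tmax))
        self.y = np.zeros((S, Tmax))
        self.obs_mask = np.zeros((S, Tmax), dtype=bool)
        self.labels = np.full((S, Tmax), "", dtype=object)
        dose_t = np.zeros((S, Dmax))
        dose_amt = np.zeros((S, Dmax))
        dose_dur = np.zeros((S, Dmax))
        iv = np.zeros((S, Dmax), dtype=bool)
        dose_mask = np.zeros((S, Dmax), dtype=bool)
        self.cov = {c: np.full(S, np.nan) for c in _COVS}

        for i, s in enumerate(dataset):
            for c in _COVS:
                self.cov[c][i] = getattr(s.covariates, c)
            for j, o in enumerate(s.observations):
                self.t[i, j] = o.time
                self.y[i, j] = np.nan if o.concentration is None else o.concentration
                self.obs_mask[i, j] = True
                self.labels[i, j] = o.label
            for j, d in enumerate(s.doses):
                dose_t[i, j] = d.time
                dose_amt[i, j] = d.amount
                dose_dur[i, j] = d.duration
                iv[i, j] = d.route == "IV"
                dose_mask[i, j] = True

        self.n_obs = self.obs_mask.sum(axis=1)
        self.dose_t = dose_t
        self.dose_amt = dose_amt
        self.dose_dur = dose_dur
        self.iv = iv
        self.dose_mask = dose_mask

        # precomputed time geometry, shape (S, Tmax, Dmax)
        dt = self.t[:, :, None] - dose_t[:, None, :]
        self._te = np.clip(dt, 0.0, dose_dur[:, None, :])
        self._td = np.maximum(dt - dose_dur[:, None, :], 0.0)
        self._dtp = np.maximum(dt, 0.0)
        active = (dt >= 0.0) & dose_mask[:, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(dose_dur > 0, dose_amt / np.where(dose_dur > 0, dose_dur, 1.0), 0.0)
        self._rate_iv = np.where(iv & dose_mask, rate, 0.0)[:, None, :]
        self._amt_im = np.where(~iv & dose_mask, dose_amt, 0.0)[:, None, :]
        self._active = active
        self._any_im = bool(np.any(~iv & dose_mask))
        # time after most recent dose start, per observation
        started = dt >= 0.0
        dt_pos = np.where(started & dose_mask[:, None, :], dt, np.inf)
        tad = np.min(dt_pos, axis=2)
        self.tad = np.where(np.isfinite(tad), tad, np.nan)

    # -- parameter evaluation ------------------------------------------------

    def typical_params(self, model: PopulationModel):
        """Arrays of typical CL (L/h) and V (L) across subjects."""
        S = self.n_subjects
        wt = self.cov["wt"]
        tcl = np.full(S, model.theta_cl)
        if model.exp_wt_cl is not None:
            tcl = tcl * (wt / 1000.0) ** model.exp_wt_cl
        if model.exp_pma_cl is not None:
            tcl = tcl * (self.cov["pma"] / 30.0) ** model.exp_pma_cl
        for term in model.extra_cl_terms:
            tcl = tcl * term.multiplier(self.cov[term.covariate.lower()])
        tv = np.full(S, model.theta_v)
        if model.exp_wt_v is not None:
            tv = tv * (wt / 1000.0) ** model.exp_wt_v
        for term in model.extra_v_terms:
            tv = tv * term.multiplier(self.cov[term.covariate.lower()])
        return tcl, tv

    # -- prediction ----------------------------------------------------------

    def pred(self, cl, v, f_im: float = 1.0, ka_im=None) -> np.ndarray:
        """Concentrations at all observation slots.

        ``cl`` and ``v`` have shape (..., S); the result has shape
        (..., S, Tmax) with zeros in padded slots.
        """
        cl = np.asarray(cl, dtype=float)
        v = np.asarray(v, dtype=float)
        k = (cl / v)[..., None, None]
        # IV terms vanish on their own before dose start (te = 0)
        e_iv = (1.0 - np.exp(-k * self._te)) * np.exp(-k * self._td)
        out = (self._rate_iv / cl[..., None, None]) * e_iv
        if self._any_im:
            if ka_im is None:
                im = (self._amt_im * f_im / v[..., None, None]) * np.exp(-k * self._dtp)
            else:
                close = np.abs(ka_im - k) < 1e-10 * np.maximum(k, 1.0)
                bateman = (
                    self._amt_im * f_im * ka_im
                    / (v[..., None, None] * np.where(close, 1.0, ka_im - k))
                    * (np.exp(-k * self._dtp) - np.exp(-ka_im * self._dtp))
                )
                limit = (
                    self._amt_im * f_im * k * self._dtp
                    * np.exp(-k * self._dtp) / v[..., None, None]
                )
                im = np.where(close, limit, bateman)
            out = out + np.where(self._active, im, 0.0)
        return out.sum(axis=-1)

    def pred_model(self, model: PopulationModel, eta_cl=0.0, eta_v=0.0) -> np.ndarray:
        """Predictions under the population model with given random effects
        (scalars or arrays broadcastable to (..., S))."""
        tcl, tv = self.typical_params(model)
        cl = tcl * np.exp(np.asarray(eta_cl, dtype=float))
        v = tv * np.exp(np.asarray(eta_v, dtype=float))
        return self.pred(cl, v, model.f_im, model.ka_im)
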