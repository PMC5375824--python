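"""Chemometric calibration engines for spectra -> leaf N (g/kg).

Four methods, implemented here rather than wrapped:

* PCR   — principal component regression: OLS on leading PC scores.
* PLSR  — PLS1 by NIPALS, mean-centred (no autoscaling); the number of
          latent factors is chosen by exact leave-one-out cross-validation
          with a one-standard-error tie-break toward fewer factors.
* SMLR  — greedy forward stepwise band selection (no backward elimination),
          entry gated by the partial-F p-value.
* BPNN  — back-propagation network on leading PC scores (smallest PC set
          carrying >= ``variance_target`` of spectral variance), one sigmoid
          hidden layer, linear output, multiple seeded restarts, model
          selection by least error on an internal hold-out.

LOO for PLSR is computed on an SVD-compressed copy of X.  This is exact,
not an approximation: PLS1 predictions depend on the training rows only
through their Gram matrix, and every leave-one-out subset's rows stay inside
the full row space, so replacing X by X·V (V from the SVD of X) changes no
fitted or held-out value.  A brute-force n-refit oracle in the test suite
confirms the equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class RegressionModel:
    """Fitted spectrum -> N predictor.

    ``coefficients`` (linear methods) are aligned to ``wavelengths`` — the
    unmasked bands of the training grid; ``network`` holds the PCA projection
    and layer weights for BPNN.  ``meta`` and ``training_record`` carry
    enough to re-apply and audit the model.
    """

    method: str
    wavelengths: np.ndarray
    intercept: float = 0.0
    coefficients: np.ndarray | None = None
    network: dict | None = None
    meta: dict = field(default_factory=dict)
    training_record: dict = field(default_factory=dict)

    # -- serialization ------------------------------------------------------
    def to_json(self, path) -> None:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        payload = {
            "method": self.method,
            "wavelengths": self.wavelengths.tolist(),
            "intercept": float(self.intercept),
            "coefficients": None if self.coefficients is None else self.coefficients.tolist(),
            "network": self.network,
            "meta": self.meta,
            "training_record": self.training_record,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=enc)

    @classmethod
    def from_json(cls, path) -> "RegressionModel":
        with open(path) as fh:
            d = json.load(fh)
        net = d["network"]
        if net is not None:
            net = {k: (np.asarray(v) if isinstance(v, list) else v) for k, v in net.items()}
        return cls(
            method=d["method"],
            wavelengths=np.asarray(d["wavelengths"], dtype=float),
            intercept=d["intercept"],
            coefficients=None if d["coefficients"] is None else np.asarray(d["coefficients"]),
            network=net,
            meta=d["meta"],
            training_record=d["training_record"],
        )


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with one y per row")
    return X, y


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------

def fit_pcr(X, y, n_components: int, wavelengths: Sequence[float] | None = None
            ) -> RegressionModel:
    """Centre, project onto leading PCs, OLS on scores, fold back to bands."""
    X, y = _as_xy(X, y)
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    x_mean, y_mean = X.mean(axis=0), y.mean()
    Xc, yc = X - x_mean, y - y_mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    if rank < n_components:
        raise ValueError(f"matrix rank {rank} below requested {n_components} components")
    # scores T = U S; OLS slope on scores is U^T y / S since T^T T = S^2
    gamma = (U[:, :n_components].T @ yc) / S[:n_components]
    beta = Vt[:n_components].T @ gamma
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    explained = (S[:n_components] ** 2) / np.sum(S**2) if S.sum() else np.zeros(n_components)
    return RegressionModel(
        method="PCR", wavelengths=wl, intercept=float(y_mean - x_mean @ beta),
        coefficients=beta,
        meta={"n_components": n_components,
              "variance_captured": float(np.sum(explained))},
    )


# ---------------------------------------------------------------------------
# PLSR (NIPALS PLS1)
# ---------------------------------------------------------------------------

def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """Weights W, loadings P, inner coefficients q for mean-centred data.

    Deflates X (and y) per extracted factor; stops early when no variance is
    left, returning however many factors were extracted.
    """
    X = Xc.copy()
    yres = yc.copy()
    W, P, q = [], [], []
    for _ in range(n_factors):
        w = X.T @ yres
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-28:
            break
        p_load = (X.T @ t) / tt
        q_a = (yres @ t) / tt
        X -= np.outer(t, p_load)
        yres = yres - q_a * t
        W.append(w)
        P.append(p_load)
        q.append(q_a)
    return (np.array(W).T if W else np.zeros((Xc.shape[1], 0)),
            np.array(P).T if P else np.zeros((Xc.shape[1], 0)),
            np.array(q))


def _pls1_predict_path(W, P, q, X0c: np.ndarray) -> np.ndarray:
    """Predicted (centred) y for rows of X0c at every factor count 1..A.

    Applies the NIPALS deflation to the new samples directly:
    t0 = x0.w_a; yhat += q_a t0; x0 -= t0 p_a.  Returns (n0, A).
    """
    X0 = X0c.copy()
    n0, A = X0.shape[0], W.shape[1]
    preds = np.zeros((n0, A))
    acc = np.zeros(n0)
    for a in range(A):
        t0 = X0 @ W[:, a]
        acc = acc + q[a] * t0
        X0 -= np.outer(t0, P[:, a])
        preds[:, a] = acc
    return preds


def _compress_rows(X: np.ndarray) -> np.ndarray:
    """Right-multiply X by its row-space basis: Z = X V, preserving the Gram."""
    n, p = X.shape
    if p <= n:
        return X
    _, S, Vt = np.linalg.svd(X, full_matrices=False)
    r = max(int(np.sum(S > S[0] * 1e-12)), 1) if S.size and S[0] > 0 else 1
    return X @ Vt[:r].T


def _loo_sq_errors(X: np.ndarray, y: np.ndarray, max_factors: int) -> np.ndarray:
    """(n, max_factors) squared LOO prediction errors for PLS1."""
    n = X.shape[0]
    Z = _compress_rows(X)
    sq_err = np.zeros((n, max_factors))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Zi, yi = Z[keep], y[keep]
        xm, ym = Zi.mean(axis=0), yi.mean()
        W, P, q = _nipals_pls1(Zi - xm, yi - ym, max_factors)
        preds = ym + _pls1_predict_path(W, P, q, (Z[i] - xm)[None, :])
        a_got = preds.shape[1]
        if a_got < max_factors:  # deflation exhausted: pad with last prediction
            preds = np.hstack([preds, np.repeat(preds[:, -1:], max_factors - a_got, axis=1)])
        sq_err[i] = (preds[0] - y[i]) ** 2
    return sq_err


def loo_cv_curve(X, y, max_factors: int) -> np.ndarray:
    """Exact leave-one-out RMSE for PLS1 at factor counts 1..max_factors."""
    X, y = _as_xy(X, y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need n >= 3 for leave-one-out")
    max_factors = min(max_factors, n - 2)
    return np.sqrt(_loo_sq_errors(X, y, max_factors).mean(axis=0))


def fit_plsr(X, y, max_factors: int = 20, n_factors: int | None = None,
             wavelengths: Sequence[float] | None = None) -> RegressionModel:
    """NIPALS PLS1 with LOO-selected factor count (unless ``n_factors`` fixed)."""
    X, y = _as_xy(X, y)
    n, p = X.shape
    max_factors = min(max_factors, n - 2, p)
    if max_factors < 1:
        raise ValueError("not enough samples/bands for one factor")
    record: dict = {}
    if n_factors is None:
        sq_err = _loo_sq_errors(X, y, max_factors)
        curve = np.sqrt(sq_err.mean(axis=0))
        best = int(np.argmin(curve))
        # one-SE tie-break toward fewer factors (delta-method SE of the RMSE)
        errs = sq_err[:, best]
        se = 0.0 if curve[best] == 0 else float(
            errs.std(ddof=1) / np.sqrt(n) / (2 * curve[best]))
        threshold = curve[best] + se
        n_factors = int(np.flatnonzero(curve <= threshold)[0]) + 1
        record["loo_rmse_curve"] = curve.tolist()
        record["loo_se_at_min"] = float(se)
    n_factors = min(n_factors, max_factors)
    x_mean, y_mean = X.mean(axis=0), y.mean()
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_factors)
    a = W.shape[1]
    # fold back: B = W (P^T W)^{-1} q
    beta = W @ np.linalg.solve(P.T @ W, q)
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    record["n_factors_extracted"] = a
    return RegressionModel(
        method="PLSR", wavelengths=wl, intercept=float(y_mean - x_mean @ beta),
        coefficients=beta, meta={"n_factors": a}, training_record=record,
    )


# ---------------------------------------------------------------------------
# SMLR
# ---------------------------------------------------------------------------

def fit_smlr(X, y, p_enter: float = 0.05, max_terms: int = 15,
             wavelengths: Sequence[float] | None = None) -> RegressionModel:
    """Greedy forward band selection; entry gated by partial-F p-value.

    At each step the band giving the largest drop in residual sum of squares
    enters, provided its partial-F p-value is below ``p_enter``; entered
    bands are never removed.  Near-collinear candidates (residual norm below
    1e-10 of the original) are skipped.
    """
    X, y = _as_xy(X, y)
    n, p = X.shape
    if max_terms >= n - 2:
        raise ValueError("max_terms must be < n - 2")
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)

    selected: list[int] = []
    path: list[dict] = []
    col_norm0 = np.einsum("ij,ij->j", X, X) + 1e-30
    # orthonormal basis of [1, X_selected]
    Q = np.ones((n, 1)) / np.sqrt(n)
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)
    if rss < 1e-24:  # constant y: nothing to explain
        return _smlr_model(X, y, [], wl, path)
    while len(selected) < max_terms:
        Xr = X - Q @ (Q.T @ X)
        norms = np.einsum("ij,ij->j", Xr, Xr)
        usable = norms > 1e-10 * col_norm0
        usable[selected] = False
        if not usable.any():
            break
        proj = Xr.T @ r
        gain = np.where(usable, proj**2 / np.where(usable, norms, 1.0), -np.inf)
        j = int(np.argmax(gain))
        ss = float(gain[j])
        df = n - len(selected) - 2  # intercept + selected + candidate
        rss_new = max(rss - ss, 0.0)
        if rss_new <= 0 or df <= 0:
            p_val = 0.0
        else:
            f_stat = ss / (rss_new / df)
            p_val = float(stats.f.sf(f_stat, 1, df))
        if p_val > p_enter:
            break
        qn = Xr[:, j] / np.sqrt(norms[j])
        Q = np.hstack([Q, qn[:, None]])
        r = r - qn * (qn @ r)
        rss = float(r @ r)
        selected.append(j)
        path.append({"wavelength_nm": float(wl[j]), "partial_f_p": p_val,
                     "rss": rss})
    return _smlr_model(X, y, selected, wl, path)


def _smlr_model(X, y, selected, wl, path) -> RegressionModel:
    n, p = X.shape
    beta = np.zeros(p)
    if selected:
        A = np.hstack([np.ones((n, 1)), X[:, selected]])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        intercept = float(coef[0])
        beta[selected] = coef[1:]
    else:
        intercept = float(np.mean(y))
    return RegressionModel(
        method="SMLR", wavelengths=np.asarray(wl, float), intercept=intercept,
        coefficients=beta,
        meta={"selected_wavelengths_nm": [float(wl[j]) for j in selected],
              "n_terms": len(selected)},
        training_record={"selection_path": path},
    )


# ---------------------------------------------------------------------------
# BPNN on PC scores
# ---------------------------------------------------------------------------

DEFAULT_TRAIN_PARAMS = {"learning_rate": 0.1, "momentum": 0.9,
                        "target_error": 1e-4, "max_iterations": 500}


def _forward(net: dict, Z: np.ndarray) -> np.ndarray:
    H = 1.0 / (1.0 + np.exp(-(Z @ net["W1"] + net["b1"])))
    return H @ net["W2"] + net["b2"]


def _train_bpnn(Z, t, hidden: int, params: dict, rng) -> tuple[dict, list[float]]:
    """Full-batch gradient-descent back-propagation; returns net and loss curve."""
    n, k = Z.shape
    net = {
        "W1": rng.normal(0, 1 / np.sqrt(k), (k, hidden)),
        "b1": np.zeros(hidden),
        "W2": rng.normal(0, 1 / np.sqrt(hidden), hidden),
        "b2": 0.0,
    }
    vel = {key: np.zeros_like(np.asarray(v, dtype=float)) for key, v in net.items()}
    lr, mom = params["learning_rate"], params["momentum"]
    curve = []
    for _ in range(int(params["max_iterations"])):
        H = 1.0 / (1.0 + np.exp(-(Z @ net["W1"] + net["b1"])))
        out = H @ net["W2"] + net["b2"]
        err = out - t
        loss = float(np.mean(err**2))
        curve.append(loss)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss")
        if loss < params["target_error"]:
            break
        d_out = 2 * err / n
        g_W2 = H.T @ d_out
        g_b2 = d_out.sum()
        d_hid = np.outer(d_out, net["W2"]) * H * (1 - H)
        g_W1 = Z.T @ d_hid
        g_b1 = d_hid.sum(axis=0)
        for key, g in (("W1", g_W1), ("b1", g_b1), ("W2", g_W2), ("b2", g_b2)):
            vel[key] = mom * vel[key] - lr * g
            net[key] = net[key] + vel[key]
    return net, curve


def fit_bpnn(X, y, variance_target: float = 0.80,
             hidden_sizes: Sequence[int] = (3, 5, 8, 12),
             n_restarts: int = 10, train_params: dict | None = None,
             rng: np.random.Generator | int | None = None,
             holdout_fraction: float = 0.2,
             wavelengths: Sequence[float] | None = None) -> RegressionModel:
    """PCA-fed back-propagation network.

    Inputs are the smallest PC set whose cumulative explained variance
    reaches ``variance_target`` (default 80%); scores are standardized.  Each
    hidden size is trained from ``n_restarts`` random initializations and the
    network with least RMSE on an internal hold-out is kept.
    """
    X, y = _as_xy(X, y)
    if not (0 < variance_target <= 1):
        raise ValueError("variance_target must be in (0, 1]")
    rng = np.random.default_rng(rng)
    n, p = X.shape
    x_mean = X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X - x_mean, full_matrices=False)
    evr = (S**2) / np.sum(S**2)
    k = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    k = min(k, np.sum(S > 1e-12))
    comps = Vt[:k]
    scores = (X - x_mean) @ comps.T
    s_mean, s_std = scores.mean(axis=0), scores.std(axis=0, ddof=1)
    s_std[s_std == 0] = 1.0
    Z = (scores - s_mean) / s_std
    y_mean, y_std = y.mean(), y.std(ddof=1) or 1.0
    t = (y - y_mean) / y_std

    n_hold = max(1, int(round(holdout_fraction * n)))
    perm = rng.permutation(n)
    hold, train = perm[:n_hold], perm[n_hold:]
    params = dict(DEFAULT_TRAIN_PARAMS, **(train_params or {}))

    best = None
    trials = []
    for hidden in hidden_sizes:
        for restart in range(n_restarts):
            try:
                net, curve = _train_bpnn(Z[train], t[train], hidden, params, rng)
            except FloatingPointError:
                trials.append({"hidden": hidden, "restart": restart, "failed": True})
                continue
            hold_rmse = float(np.sqrt(np.mean((_forward(net, Z[hold]) - t[hold]) ** 2)))
            trials.append({"hidden": hidden, "restart": restart,
                           "holdout_rmse": hold_rmse, "final_loss": curve[-1] if curve else None})
            if best is None or hold_rmse < best[0]:
                best = (hold_rmse, hidden, net, curve)
    if best is None:
        raise RuntimeError("all BPNN restarts diverged")
    hold_rmse, hidden, net, curve = best
    wl = np.arange(p, dtype=float) if wavelengths is None else np.asarray(wavelengths, float)
    network = {
        "x_mean": x_mean, "components": comps, "score_mean": s_mean,
        "score_std": s_std, "y_mean": float(y_mean), "y_std": float(y_std),
        "W1": net["W1"], "b1": net["b1"], "W2": net["W2"], "b2": float(net["b2"]),
    }
    return RegressionModel(
        method="BPNN", wavelengths=wl, network=network,
        meta={"n_components": int(k), "variance_captured": float(np.cumsum(evr)[k - 1]),
              "hidden_size": int(hidden), "n_restarts": int(n_restarts),
              "holdout_rmse_std_scale": hold_rmse},
        training_record={"loss_curve": [float(c) for c in curve[-50:]],
                         "trials": trials},
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict(model: RegressionModel, X) -> np.ndarray:
    """Apply a fitted model to new spectra on the training band grid."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.wavelengths.size:
        raise ValueError(
            f"grid mismatch: model expects {model.wavelengths.size} bands, got {X.shape[1]}")
    if model.network is not None:
        net = model.network
        Z = ((X - net["x_mean"]) @ np.asarray(net["components"]).T - net["score_mean"]) \
            / net["score_std"]
        out = _forward({"W1": np.asarray(net["W1"]), "b1": np.asarray(net["b1"]),
                        "W2": np.asarray(net["W2"]), "b2": net["b2"]}, Z)
        return out * net["y_std"] + net["y_mean"]
    if model.coefficients is None:
        return np.full(X.shape[0], model.intercept)
    return X @ model.coefficients + model.intercept
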