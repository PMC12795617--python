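"""Two-step quasi-likelihood model selection and model-averaged surfaces.

Workflow, applied first to detection (p) with occupancy held at its null
structure, then to occupancy (psi) with the best detection structure held
fixed:

1.  fit the global additive model, then drop every covariate whose standard
    error is at least as large as the magnitude of its coefficient;
2.  estimate overdispersion c-hat on the simplified global model with a
    MacKenzie-Bailey parametric bootstrap of the detection-history Pearson
    chi-square;
3.  fit the null and all additive combinations of the remaining covariates
    (collinear pairs, |r| >= 0.6, never co-occur), rank by QAICc
    (quasi-log-likelihood = logL / c-hat, small-sample corrected with
    n = number of sites), and retain the models with dQAICc <= 2;
4.  model-average predicted occupancy over the retained set with
    renormalized Akaike weights, excluding grid cells more than three
    quarters covered by waterbodies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import DetectionMatrix
from .occupancy import (
    Covariates,
    ModelSpec,
    OccupancyFit,
    fit_occupancy,
    fitted_psi_p,
    predict_psi,
    simulate_binary_from,
)

logger = logging.getLogger(__name__)


def simplify_global(fit: OccupancyFit, side: str) -> tuple[str, ...]:
    """Reduce a global model: drop covariates whose SE >= |beta|.

    Intercepts are always kept.  If the global fit did not converge the
    step is skipped (the full covariate list is returned) with a warning.
    """
    if side not in ("psi", "p"):
        raise ValueError("side must be 'psi' or 'p'")
    covs = fit.spec.psi_covariates if side == "psi" else fit.spec.p_covariates
    if not fit.converged:
        logger.warning(
            "global model %s not converged; simplification skipped", fit.spec.label()
        )
        return covs
    est = fit.beta_psi if side == "psi" else fit.beta_p
    se = fit.se_psi if side == "psi" else fit.se_p
    return tuple(c for c in covs if se[c] < abs(est[c]))


# ---------------------------------------------------------------------------
# goodness of fit


def _mb_chisq(psi: np.ndarray, p: np.ndarray, y: np.ndarray, mask: np.ndarray) -> float:
    """MacKenzie-Bailey Pearson chi-square over detection-history cohorts.

    Sites are grouped by their missingness pattern (cohort); within a
    cohort every possible binary history is a cell with expected count
    summed over the cohort's sites under the fitted (psi, p).
    """
    n, J = y.shape
    patterns: dict[tuple[int, ...], list[int]] = {}
    for i in range(n):
        obs = tuple(np.flatnonzero(mask[i]))
        patterns.setdefault(obs, []).append(i)

    chi2 = 0.0
    for obs, idx in patterns.items():
        k = len(obs)
        if k == 0:
            continue
        idx = np.array(idx)
        pk = p[np.ix_(idx, list(obs))]  # (m, k)
        psik = psi[idx]
        histories = np.array(list(itertools.product((0, 1), repeat=k)), dtype=float)
        # P(history | site): psi * prod p^h (1-p)^(1-h)  (+ (1-psi) for all-zero)
        lp = histories @ np.log(np.clip(pk, 1e-12, None)).T + (
            1 - histories
        ) @ np.log(np.clip(1 - pk, 1e-12, None)).T  # (H, m)
        prob = psik[None, :] * np.exp(lp)
        allzero = ~histories.any(axis=1)
        prob[allzero] += 1 - psik[None, :]
        expected = prob.sum(axis=1)

        yk = y[np.ix_(idx, list(obs))]
        codes = (yk @ (2 ** np.arange(k - 1, -1, -1))).astype(int)
        hist_codes = (histories @ (2 ** np.arange(k - 1, -1, -1))).astype(int)
        observed = np.array([(codes == c).sum() for c in hist_codes], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cells = (observed - expected) ** 2 / np.maximum(expected, 1e-10)
        chi2 += float(cells.sum())
    return chi2


@dataclass
class GofResult:
    c_hat: float
    c_hat_raw: float
    chi2_observed: float
    chi2_boot_mean: float
    p_value: float
    n_boot: int


def gof_chat(
    fit: OccupancyFit,
    m: DetectionMatrix,
    cov: Covariates,
    B: int = 1000,
    seed: int = 0,
    n_starts_refit: int = 2,
) -> GofResult:
    """Parametric-bootstrap overdispersion factor for a fitted model.

    c-hat is the observed chi-square divided by the mean bootstrap
    chi-square, floored at 1 (underdispersion is not credited).
    Deterministic given *seed*.
    """
    if B < 1:
        raise ValueError("bootstrap replicate count B must be >= 1")
    if B < 100:
        logger.warning("B=%d bootstrap replicates is small; >=100 recommended", B)
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged model")

    psi, p, mask = fitted_psi_p(fit, m, cov)
    y = np.where(mask, m.binary, 0.0)
    rows = {tuple(r) for r in np.column_stack([y, mask]).tolist()}
    if len(rows) < 2:
        raise ValueError("degenerate data: a single unique detection history")
    chi2_obs = _mb_chisq(psi, p, y, mask)

    rng = np.random.default_rng(seed)
    boot = np.empty(B)
    for bi in range(B):
        yb = simulate_binary_from(psi, p, mask, rng)
        # encode simulated detections as certain detections so the binary
        # collapse reproduces yb exactly
        mb = DetectionMatrix(
            species=m.species,
            site_ids=m.site_ids,
            states=yb * 2.0,
            detection_covariates=m.detection_covariates,
        )
        refit = fit_occupancy(
            mb, cov, fit.spec,
            n_starts=n_starts_refit,
            seed=int(rng.integers(2**31 - 1)),
            start=fit.params,
        )
        psib, pb, maskb = fitted_psi_p(refit, mb, cov)
        boot[bi] = _mb_chisq(psib, pb, np.where(maskb, yb, 0.0), maskb)

    mean_boot = float(boot.mean())
    raw = chi2_obs / mean_boot if mean_boot > 0 else np.inf
    return GofResult(
        c_hat=max(1.0, raw),
        c_hat_raw=raw,
        chi2_observed=chi2_obs,
        chi2_boot_mean=mean_boot,
        p_value=float((boot >= chi2_obs).mean()),
        n_boot=B,
    )


# ---------------------------------------------------------------------------
# QAICc ladders


def qaicc(quasi_loglik: float, K: int, n: int) -> float:
    """Small-sample quasi-likelihood information criterion.

    ``-2*qll + 2K + 2K(K+1)/(n-K-1)`` with qll = logL / c-hat, K the
    parameter count including the variance-inflation slot, and n the number
    of sites.
    """
    if n <= K + 1:
        raise ValueError(f"n={n} must exceed K+1={K + 1}")
    return -2.0 * quasi_loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(delta: np.ndarray) -> np.ndarray:
    w = np.exp(-np.asarray(delta, dtype=float) / 2.0)
    return w / w.sum()


@dataclass
class ModelLadder:
    """A ranked candidate set with QAICc, weights and the dQAICc <= 2 set."""

    table: pd.DataFrame  # model, K, QAICc, dQAICc, weight, cum_weight, qll
    fits: dict[str, OccupancyFit]
    c_hat: float
    n: int
    delta_retain: float = 2.0

    @property
    def retained(self) -> list[OccupancyFit]:
        keep = self.table[self.table["dQAICc"] <= self.delta_retain]
        return [self.fits[lbl] for lbl in keep["model"]]

    @property
    def retained_weights(self) -> np.ndarray:
        keep = self.table[self.table["dQAICc"] <= self.delta_retain]
        w = keep["weight"].to_numpy()
        return w / w.sum()

    @property
    def best(self) -> OccupancyFit:
        return self.fits[self.table.iloc[0]["model"]]


def ladder(
    fits: list[OccupancyFit],
    c_hat: float,
    n: int | None = None,
    delta_retain: float = 2.0,
) -> ModelLadder:
    """Rank converged fits by QAICc.

    Non-converged fits are excluded before ranking (a model with
    convergence issues never enters the comparison).  Weights are Akaike
    weights over the full converged ladder; the retained set keeps
    dQAICc <= *delta_retain* (inclusive).
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits to rank")
    n = ok[0].n_sites if n is None else n
    qll = np.array([f.log_likelihood / c_hat for f in ok])
    q = np.array([qaicc(ql, f.K, n) for ql, f in zip(qll, ok)])
    order = np.argsort(q, kind="stable")
    q, qll = q[order], qll[order]
    ok = [ok[i] for i in order]
    delta = q - q[0]
    w = akaike_weights(delta)
    for f in ok:
        f.c_hat_applied = c_hat
    table = pd.DataFrame(
        {
            "model": [f.spec.label() for f in ok],
            "K": [f.K for f in ok],
            "QAICc": q,
            "dQAICc": delta,
            "weight": w,
            "cum_weight": np.cumsum(w),
            "quasi_loglik": qll,
        }
    )
    return ModelLadder(
        table=table,
        fits={f.spec.label(): f for f in ok},
        c_hat=c_hat,
        n=n,
        delta_retain=delta_retain,
    )


def ladder_from_deltas(deltas) -> np.ndarray:
    """Akaike weights directly from a dQAICc column (utility for checking a
    published ladder)."""
    return akaike_weights(np.asarray(deltas, dtype=float))


def candidate_set(
    eligible: tuple[str, ...],
    incompatible: frozenset[frozenset[str]] = frozenset(),
) -> list[tuple[str, ...]]:
    """All subsets of the eligible covariates (the empty subset is the null
    model), excluding any subset containing a collinear pair."""
    out: list[tuple[str, ...]] = []
    for r in range(len(eligible) + 1):
        for combo in itertools.combinations(eligible, r):
            s = set(combo)
            if any(pair <= s for pair in incompatible):
                continue
            out.append(combo)
    return out


def resolve_incompatible(
    menu: tuple[str, ...],
    incompatible: frozenset[frozenset[str]],
    priority: tuple[str, ...] | None = None,
) -> tuple[str, ...]:
    """Drop the lower-priority member of each collinear pair so a global
    additive model can be formed.  Priority defaults to menu order."""
    order = {c: i for i, c in enumerate(priority or menu)}
    keep = list(menu)
    for pair in incompatible:
        both = [c for c in keep if c in pair]
        if len(both) == 2:
            drop = max(both, key=lambda c: order.get(c, len(order)))
            keep.remove(drop)
            logger.info("dropping %s from the global model (collinear pair)", drop)
    return tuple(keep)


# ---------------------------------------------------------------------------
# two-step selection


@dataclass
class TwoStepResult:
    p_ladder: ModelLadder
    psi_ladder: ModelLadder
    best_p_spec: tuple[str, ...]
    gof_p: GofResult | None
    gof_psi: GofResult | None

    @property
    def retained(self) -> list[OccupancyFit]:
        return self.psi_ladder.retained


def _stage_chat(
    m: DetectionMatrix,
    cov: Covariates,
    global_spec: ModelSpec,
    simplified_spec: ModelSpec,
    B: int,
    seed: int,
    n_starts: int,
) -> tuple[GofResult | None, float, OccupancyFit]:
    """Fit the simplified global model and estimate c-hat on it, falling
    back to c-hat = 1 when no suitable model converges."""
    sfit = fit_occupancy(m, cov, simplified_spec, n_starts=n_starts, seed=seed)
    gof_target = sfit
    if not sfit.converged:
        gfit = fit_occupancy(m, cov, global_spec, n_starts=n_starts, seed=seed + 1)
        gof_target = gfit if gfit.converged else None
    if gof_target is None:
        logger.warning("no converged global model; using c-hat = 1")
        return None, 1.0, sfit
    try:
        gof = gof_chat(gof_target, m, cov, B=B, seed=seed + 2)
    except ValueError as exc:
        logger.warning("goodness of fit unavailable (%s); using c-hat = 1", exc)
        return None, 1.0, sfit
    return gof, gof.c_hat, sfit


def two_step_select(
    m: DetectionMatrix,
    cov: Covariates,
    p_menu: tuple[str, ...],
    psi_menu: tuple[str, ...],
    B: int = 1000,
    seed: int = 0,
    n_starts: int = 10,
    delta_retain: float = 2.0,
    priority: tuple[str, ...] | None = None,
) -> TwoStepResult:
    """Two-step selection: detection structure first (occupancy at null),
    then occupancy structure with the best detection model held fixed."""
    # ---- stage 1: detection
    p_global = resolve_incompatible(p_menu, cov.incompatible, priority)
    gspec = ModelSpec(psi_covariates=(), p_covariates=p_global)
    gfit = fit_occupancy(m, cov, gspec, n_starts=n_starts, seed=seed)
    p_eligible = simplify_global(gfit, "p")
    sspec = ModelSpec(psi_covariates=(), p_covariates=p_eligible)
    gof_p, chat_p, _ = _stage_chat(m, cov, gspec, sspec, B, seed + 10, n_starts)

    p_fits = []
    for combo in candidate_set(p_eligible, cov.incompatible):
        spec = ModelSpec(psi_covariates=(), p_covariates=combo)
        p_fits.append(fit_occupancy(m, cov, spec, n_starts=n_starts, seed=seed + 20))
    p_lad = ladder(p_fits, chat_p, delta_retain=delta_retain)
    best_p = p_lad.best.spec.p_covariates

    # ---- stage 2: occupancy
    psi_global = resolve_incompatible(psi_menu, cov.incompatible, priority)
    gspec2 = ModelSpec(psi_covariates=psi_global, p_covariates=best_p)
    gfit2 = fit_occupancy(m, cov, gspec2, n_starts=n_starts, seed=seed + 30)
    psi_eligible = simplify_global(gfit2, "psi")
    sspec2 = ModelSpec(psi_covariates=psi_eligible, p_covariates=best_p)
    gof_psi, chat_psi, _ = _stage_chat(m, cov, gspec2, sspec2, B, seed + 40, n_starts)

    psi_fits = []
    for combo in candidate_set(psi_eligible, cov.incompatible):
        spec = ModelSpec(psi_covariates=combo, p_covariates=best_p)
        psi_fits.append(fit_occupancy(m, cov, spec, n_starts=n_starts, seed=seed + 50))
    psi_lad = ladder(psi_fits, chat_psi, delta_retain=delta_retain)

    return TwoStepResult(
        p_ladder=p_lad,
        psi_ladder=psi_lad,
        best_p_spec=best_p,
        gof_p=gof_p,
        gof_psi=gof_psi,
    )


# ---------------------------------------------------------------------------
# model averaging


@dataclass
class AveragedSurface:
    """Model-averaged occupancy surface over the district grid."""

    table: pd.DataFrame  # index grid_id: psi, se, excluded, reason
    district_mean: float
    district_se: float
    mean_grid_se: float
    excluded_grids: list[str] = field(default_factory=list)
    weights: np.ndarray | None = None


def model_average(
    lad: ModelLadder,
    site_rows: pd.DataFrame,
    water_fraction: pd.Series | None = None,
    water_threshold: float = 0.75,
) -> AveragedSurface:
    """Average predicted occupancy over the retained (dQAICc <= 2) models.

    Weights are the retained Akaike weights renormalized to one.  Per-grid
    SE uses the unconditional (within + between model) variance.  Grid
    cells with more than *water_threshold* of their area under waterbodies
    are excluded from the surface and the district summary.

    The district summary is the mean of per-grid averaged psi over included
    cells; its SE is the delta-method SE of that spatial mean (grids
    treated as fixed), averaged over models with the same weights.  The
    mean of per-grid SEs is also reported.
    """
    fits = lad.retained
    if not fits:
        raise ValueError("empty retained set")
    w = lad.retained_weights

    preds = [predict_psi(f, site_rows) for f in fits]
    psi_k = np.column_stack([pr["psi"].to_numpy() for pr in preds])  # (G, M)
    var_k = np.column_stack([pr["se"].to_numpy() ** 2 for pr in preds])

    psi_bar = psi_k @ w
    var_bar = (var_k + (psi_k - psi_bar[:, None]) ** 2) @ w
    se_bar = np.sqrt(var_bar)

    if water_fraction is not None:
        wf = water_fraction.reindex(site_rows.index).fillna(0.0).to_numpy()
    else:
        wf = np.zeros(len(site_rows))
    excluded = wf > water_threshold

    table = pd.DataFrame(
        {
            "psi": psi_bar,
            "se": se_bar,
            "excluded": excluded,
            "reason": np.where(excluded, "waterbody", ""),
        },
        index=site_rows.index,
    )

    inc = ~excluded
    G = int(inc.sum())
    if G == 0:
        raise ValueError("all grids excluded")
    district_mean = float(psi_bar[inc].mean())

    # delta-method variance of the spatial mean, per model, then averaged
    # with the between-model spread of the per-model means
    mean_vars, mean_ests = [], []
    for f in fits:
        k = 1 + len(f.spec.psi_covariates)
        X = np.column_stack(
            [np.ones(G)]
            + [site_rows.loc[inc, c].to_numpy(dtype=float) for c in f.spec.psi_covariates]
        )
        eta = X @ f.params[:k]
        psi = 1 / (1 + np.exp(-eta))
        grad = (psi * (1 - psi))[:, None] * X  # d mean / d beta, up to 1/G
        gbar = grad.mean(axis=0)
        V = f.vcov[:k, :k] if f.vcov is not None else np.zeros((k, k))
        mean_vars.append(float(gbar @ V @ gbar))
        mean_ests.append(float(psi.mean()))
    mean_vars = np.array(mean_vars)
    mean_ests = np.array(mean_ests)
    district_var = float(
        (mean_vars + (mean_ests - district_mean) ** 2) @ w
    )

    return AveragedSurface(
        table=table,
        district_mean=district_mean,
        district_se=float(np.sqrt(district_var)),
        mean_grid_se=float(se_bar[inc].mean()),
        excluded_grids=list(site_rows.index[excluded]),
        weights=w,
    )
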